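"""Gaussian linear mixed models by REML for unbalanced trial data.

Fits models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),
    e ~ N(0, R),  R = diag(sigma2_{g(i)}),

i.e. arbitrary crossed/nested categorical random terms, each with a single
variance component, and group-wise heterogeneous residual variances (one
variance per level of a grouping factor, e.g. one per location-year
environment).  This is the model family used for combined analyses of
multi-environment maize hybrid trials: hybrids and years fixed, replicates,
incomplete blocks, hybrid-by-year and location-within-year effects random,
and a separate residual variance per environment.

The restricted likelihood is evaluated through the mixed-model equations
(MME).  With W = [X Z], D = blockdiag(0, G^-1) and C = W'R^-1 W + D,

    -2 l_R = (n-p) log 2*pi + log|R| + log|G| + log|C| + y'Py,

and the REML score for a variance parameter theta with dV/dtheta = V_dot is

    d(-2 l_R)/dtheta = tr(P V_dot) - y'P V_dot P y,

where P = R^-1 - R^-1 W C^-1 W' R^-1.  All traces are reduced to the diagonal
of C^-1, so one Cholesky factorisation and one inverse of C per evaluation
give the criterion and the full analytic gradient.  Optimisation is
quasi-Newton (L-BFGS-B) on log-variances, which keeps iterates positive and
lets boundary components decay smoothly to (numerical) zero; a Nelder-Mead
fallback handles the rare non-convergent case.  Components that finish below
a relative floor are reported as 0 with a boundary flag.

Fixed factors use sum-to-zero contrasts so the intercept is the equally
weighted grand mean and adjusted means (least-squares means) are simple
contrasts of the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

__all__ = [
    "ModelSpec",
    "LmmFit",
    "AdjustedMean",
    "fit_lmm",
    "adjusted_means",
    "blup_pev",
    "ConvergenceError",
]

#: relative floor below which a variance component is a boundary zero
_BOUNDARY_REL = 1e-7
#: hard floor for variances on the standardized scale (keeps C well posed)
_VAR_FLOOR = 1e-10


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: Any = None):
        super().__init__(message)
        self.trace = trace


def _as_term(term: str | Sequence[str]) -> tuple[str, ...]:
    """Normalize a term to a tuple of column names ('a:b' -> ('a','b'))."""
    if isinstance(term, str):
        return tuple(t.strip() for t in term.split(":"))
    return tuple(term)


def term_label(term: str | Sequence[str]) -> str:
    return ":".join(_as_term(term))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification over a long-format table.

    Parameters
    ----------
    response
        Column holding the (numeric) response.
    fixed_terms
        Categorical factors treated as fixed (sum-to-zero coded); the
        intercept is always included.
    random_terms
        Factors or ':'-joined interactions, one variance component each.
    residual_groups
        Factor (or ':'-joined combination) whose observed levels each get
        their own residual variance; ``None`` means a single variance.
    pool_small_groups
        Residual groups with fewer observations than this are pooled with
        the group whose mean response is nearest (0 disables pooling).
    """

    response: str
    fixed_terms: tuple = ()
    random_terms: tuple = ()
    residual_groups: str | tuple | None = None
    pool_small_groups: int = 5

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))
        fixed = {term_label(t) for t in self.fixed_terms}
        rand = {term_label(t) for t in self.random_terms}
        both = fixed & rand
        if both:
            raise ValueError(f"terms both fixed and random: {sorted(both)}")


@dataclass
class AdjustedMean:
    """Stage-1 BLUE of one factor level with its standard error."""

    level: Any
    estimate: float
    se: float


@dataclass
class LmmFit:
    """A fitted mixed model (REML)."""

    spec: ModelSpec
    n_obs: int
    varcomp: dict[str, float]
    residual_varcomp: dict[Any, float]
    boundary: set
    converged: bool
    n_iter: int
    reml_loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_levels: dict[str, list]
    fixed_slices: dict[str, slice]
    blup_tables: dict[str, pd.DataFrame]
    rank_deficient: bool = False
    message: str = ""
    # internals
    _blup_cov: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _objective: Callable[[np.ndarray], float] | None = field(
        default=None, repr=False
    )
    _theta: np.ndarray | None = field(default=None, repr=False)
    theta_names: list[str] = field(default_factory=list, repr=False)

    def objective(self, theta: np.ndarray) -> float:
        """-2 REML log-likelihood at natural-scale variances ``theta``.

        Parameter order is ``theta_names`` (random terms, then residual
        groups).  Used by grid-search cross-checks and delta-method SEs.
        """
        if self._objective is None:
            raise ValueError("objective unavailable for a degenerate fit")
        return self._objective(np.asarray(theta, dtype=float))


def _factor_codes(data: pd.DataFrame, term: tuple[str, ...]):
    """(codes, levels) for the observed level combinations of a term."""
    for col in term:
        if col not in data.columns:
            raise KeyError(f"factor column {col!r} not in table")
    if len(term) == 1:
        keys = data[term[0]]
    else:
        keys = pd.Series(list(zip(*(data[c] for c in term))), index=data.index)
    cat = pd.Categorical(keys)
    return np.asarray(cat.codes), list(cat.categories)


def _build_fixed(data: pd.DataFrame, fixed_terms) -> tuple[
    np.ndarray, dict[str, list], dict[str, slice]
]:
    """Sum-to-zero fixed design with intercept."""
    n = len(data)
    cols = [np.ones((n, 1))]
    levels: dict[str, list] = {}
    slices: dict[str, slice] = {}
    start = 1
    for t in fixed_terms:
        term = _as_term(t)
        lab = term_label(term)
        codes, levs = _factor_codes(data, term)
        L = len(levs)
        if L < 2:
            levels[lab] = levs
            slices[lab] = slice(start, start)
            continue
        M = np.zeros((n, L - 1))
        inner = codes < L - 1
        M[np.arange(n)[inner], codes[inner]] = 1.0
        M[codes == L - 1, :] = -1.0
        cols.append(M)
        levels[lab] = levs
        slices[lab] = slice(start, start + L - 1)
        start += L - 1
    return np.hstack(cols), levels, slices


def _build_random(data: pd.DataFrame, random_terms):
    """Sparse indicator blocks for every random term."""
    n = len(data)
    blocks, labels, level_lists, sizes = [], [], [], []
    for t in random_terms:
        term = _as_term(t)
        lab = term_label(term)
        codes, levs = _factor_codes(data, term)
        q = len(levs)
        Z = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, q)
        )
        blocks.append(Z)
        labels.append(lab)
        level_lists.append(levs)
        sizes.append(q)
    return blocks, labels, level_lists, sizes


def _residual_group_index(data: pd.DataFrame, spec: ModelSpec, y: np.ndarray):
    """Row -> residual-group index, pooling undersized groups."""
    if spec.residual_groups is None:
        return np.zeros(len(data), dtype=int), ["all"]
    term = _as_term(spec.residual_groups)
    codes, levs = _factor_codes(data, term)
    counts = np.bincount(codes, minlength=len(levs))
    min_n = spec.pool_small_groups
    if min_n and (counts < min_n).any() and len(levs) > 1:
        gmeans = np.array(
            [y[codes == g].mean() if counts[g] else np.nan
             for g in range(len(levs))]
        )
        merged = {}
        big = [g for g in range(len(levs)) if counts[g] >= min_n]
        if not big:  # everything small: single pooled group
            return np.zeros(len(data), dtype=int), ["pooled"]
        for g in range(len(levs)):
            if counts[g] < min_n:
                tgt = min(big, key=lambda b: abs(gmeans[b] - gmeans[g]))
                merged[g] = tgt
                warnings.warn(
                    f"residual group {levs[g]!r} has {counts[g]} obs; "
                    f"pooled with {levs[tgt]!r}",
                    stacklevel=3,
                )
            else:
                merged[g] = g
        remap = {}
        new_levels = []
        new_codes = np.empty_like(codes)
        for g in range(len(levs)):
            tgt = merged[g]
            if tgt not in remap:
                remap[tgt] = len(new_levels)
                new_levels.append(levs[tgt])
            new_codes[codes == g] = remap[tgt]
        return new_codes, new_levels
    return codes, list(levs)


def _degenerate_fit(data, spec, y, X, fixed_levels, fixed_slices,
                    rand_labels, rand_levels, group_levels) -> LmmFit:
    """All-zero-variance fit for a constant response."""
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = float(y[0]) if len(y) else 0.0
    blups = {
        lab: pd.DataFrame(
            {"level": levs, "blup": 0.0, "pev": 0.0}
        )
        for lab, levs in zip(rand_labels, rand_levels)
    }
    return LmmFit(
        spec=spec,
        n_obs=len(y),
        varcomp={lab: 0.0 for lab in rand_labels},
        residual_varcomp={g: 0.0 for g in group_levels},
        boundary=set(rand_labels) | set(group_levels),
        converged=True,
        n_iter=0,
        reml_loglik=np.nan,
        beta=beta,
        beta_cov=np.zeros((p, p)),
        fixed_levels=fixed_levels,
        fixed_slices=fixed_slices,
        blup_tables=blups,
        _blup_cov={lab: np.zeros((len(levs), len(levs)))
                   for lab, levs in zip(rand_labels, rand_levels)},
        message="constant response; all components at zero",
    )


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
    start: Mapping[str, float] | None = None,
) -> LmmFit:
    """Fit ``spec`` to ``data`` by REML.

    Rows with a missing response are dropped.  Deterministic: starting
    values are fixed (every component at half the response variance,
    unless ``start`` supplies original-scale variances keyed like
    ``theta_names``) and no randomness is used.  A warm ``start`` from a
    structurally similar fit speeds up batch sweeps without changing the
    optimum.

    Raises
    ------
    ConvergenceError
        If neither the quasi-Newton pass nor the derivative-free fallback
        reaches the convergence tolerance within ``max_iter`` iterations.
    """
    data = data.loc[data[spec.response].notna()].reset_index(drop=True)
    n = len(data)
    if n == 0:
        raise ValueError("no non-missing observations for the response")
    y_raw = np.asarray(data[spec.response], dtype=float)

    X, fixed_levels, fixed_slices = _build_fixed(data, spec.fixed_terms)
    Zs, rand_labels, rand_levels, q_sizes = _build_random(
        data, spec.random_terms
    )
    group_idx, group_levels = _residual_group_index(data, spec, y_raw)
    G = len(group_levels)
    K = len(Zs)
    p = X.shape[1]
    if n - p < 1:
        raise ValueError(
            f"no residual degrees of freedom (n={n}, fixed rank<= {p})"
        )

    scale = float(np.std(y_raw, ddof=1)) if n > 1 else 0.0
    if scale == 0.0:
        return _degenerate_fit(
            data, spec, y_raw, X, fixed_levels, fixed_slices,
            rand_labels, rand_levels, group_levels,
        )
    offset = float(np.mean(y_raw))
    y = (y_raw - offset) / scale

    W = sparse.hstack([sparse.csr_matrix(X)] + Zs, format="csr")
    m = W.shape[1]
    q_total = m - p
    # index blocks of theta / of W columns
    blk = []
    col = p
    for q in q_sizes:
        blk.append(slice(col, col + q))
        col += q
    grp_rows = [np.where(group_idx == g)[0] for g in range(G)]
    grp_n = np.array([len(r) for r in grp_rows], dtype=float)
    Wt = W.T.tocsr()

    rank_flag = False

    def crit_grad(theta: np.ndarray, want_grad: bool, want_fit: bool):
        """-2 l_R (without the 2*pi constant), gradient, and fit pieces."""
        nonlocal rank_flag
        sig_k = theta[:K]
        sig_g = theta[K:]
        rinv = 1.0 / sig_g[group_idx]
        Wr = W.multiply(rinv[:, None]).tocsr()
        A = (Wt @ Wr).toarray()
        C = A.copy()
        d = np.zeros(m)
        for k in range(K):
            d[blk[k]] = 1.0 / sig_k[k]
        C[np.arange(m), np.arange(m)] += d
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            # near-singular C: rank-deficient fixed design or an extreme
            # variance iterate; a tiny ridge restores definiteness
            ridge = 1e-8 * max(1.0, float(np.abs(np.diag(C)).max()))
            C[np.arange(m), np.arange(m)] += ridge
            try:
                cf = linalg.cho_factor(C, lower=True, check_finite=False)
                if want_fit:  # flag only when it happens at the optimum
                    rank_flag = True
            except linalg.LinAlgError:
                if want_fit:
                    raise ConvergenceError(
                        "mixed-model equations singular at the optimum"
                    )
                bad = np.full(K + G, 0.0) if want_grad else None
                return np.inf, bad, None
        rhs = Wt @ (y * rinv)
        bhat = linalg.cho_solve(cf, rhs, check_finite=False)
        resid = y - W @ bhat
        py = resid * rinv
        ypy = float(y @ py)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdetR = float(grp_n @ np.log(sig_g))
        logdetG = float(np.array(q_sizes) @ np.log(sig_k)) if K else 0.0
        f = logdetR + logdetG + logdetC + ypy

        grad = None
        Binv = None
        if want_grad or want_fit:
            # dpotri: inverse from the Cholesky factor in place
            inv_l, info = linalg.lapack.dpotri(cf[0], lower=True)
            if info != 0:
                Binv = linalg.cho_solve(cf, np.eye(m), check_finite=False)
            else:
                lo = np.tril(inv_l)
                Binv = lo + lo.T - np.diag(np.diag(lo))
        if want_grad:
            diagB = np.diag(Binv)
            u = Wt @ py
            grad = np.empty(K + G)
            for k in range(K):
                s = blk[k]
                tr = (q_sizes[k] - diagB[s].sum() / sig_k[k]) / sig_k[k]
                grad[k] = tr - float(u[s] @ u[s])
            if G == 1:
                # tr(P) = [n - (p+q) + tr(C^-1 D)] / sigma2_e
                trCD = float(sum(
                    diagB[blk[k]].sum() / sig_k[k] for k in range(K)
                ))
                trP = (n - m + trCD) / sig_g[0]
                grad[K] = trP - float(py @ py)
            elif G:
                WB = W @ Binv          # n x m dense
                rowquad = np.asarray(
                    W.multiply(WB).sum(axis=1)
                ).ravel()
                for g in range(G):
                    rows = grp_rows[g]
                    trP = (rinv[rows]
                           - rinv[rows] ** 2 * rowquad[rows]).sum()
                    grad[K + g] = trP - float(py[rows] @ py[rows])
        pieces = None
        if want_fit:
            pieces = (bhat, Binv)
        return f, grad, pieces

    theta0 = np.full(K + G, 0.5)  # half the (unit) response variance
    if start:
        names = list(rand_labels) + [f"resid:{g}" for g in group_levels]
        for j, name in enumerate(names):
            if name in start:
                theta0[j] = np.clip(start[name] / (scale**2), 1e-6, 1e5)
    lo, hi = np.log(_VAR_FLOOR), np.log(1e6)
    bounds = [(lo, hi)] * (K + G)

    def fun_log(phi):
        theta = np.exp(phi)
        f, g, _ = crit_grad(theta, True, False)
        return f, g * theta  # chain rule to log scale

    def run_lbfgs(phi0):
        return optimize.minimize(
            fun_log,
            phi0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": min(tol, 1e-13),
                     "gtol": 1e-9, "maxls": 40},
        )

    def stalled(res):
        """True when the reported stop is not a stationary point (a
        failed first line search can trigger the ftol test in place)."""
        if not np.isfinite(res.fun):
            return True
        pg = np.asarray(res.jac, dtype=float).copy()
        at_lo = res.x <= lo + 1e-8
        at_hi = res.x >= hi - 1e-8
        pg[at_lo & (pg > 0)] = 0.0
        pg[at_hi & (pg < 0)] = 0.0
        return float(np.max(np.abs(pg))) > 2.0

    res = run_lbfgs(np.log(theta0))
    n_iter = int(res.nit)
    if not res.success or stalled(res):
        # restart from the fixed default start; keep the better optimum
        res_d = run_lbfgs(np.log(np.full(K + G, 0.5)))
        n_iter += int(res_d.nit)
        if res_d.fun <= res.fun or not np.isfinite(res.fun):
            res = res_d
    converged = bool(res.success) and not stalled(res)
    if not converged:
        # derivative-free fallback from the quasi-Newton iterate
        res2 = optimize.minimize(
            lambda phi: crit_grad(np.exp(phi), False, False)[0],
            res.x,
            method="Nelder-Mead",
            options={"maxiter": max_iter * (K + G) * 4,
                     "fatol": tol, "xatol": 1e-6},
        )
        if res2.fun <= res.fun:
            res = res2
        converged = bool(res2.success) or bool(res.success)
        n_iter += int(res2.nit)
        if not converged and not np.isfinite(res.fun):
            raise ConvergenceError(
                "REML failed to reach a finite optimum", trace=res
            )

    theta_hat = np.exp(res.x)
    f_std, _, pieces = crit_grad(theta_hat, False, True)
    bhat_std, Binv = pieces

    # back-transform to the original response scale
    s2 = scale**2
    varcomp = {lab: float(theta_hat[k] * s2)
               for k, lab in enumerate(rand_labels)}
    resvar = {group_levels[g]: float(theta_hat[K + g] * s2)
              for g in range(G)}
    boundary = set()
    for k, lab in enumerate(rand_labels):
        if theta_hat[k] < _BOUNDARY_REL:
            varcomp[lab] = 0.0
            boundary.add(lab)
    for g, lev in enumerate(group_levels):
        if theta_hat[K + g] < _BOUNDARY_REL:
            boundary.add(lev)

    beta = bhat_std[:p] * scale
    beta[0] += offset
    beta_cov = Binv[:p, :p] * s2

    blups: dict[str, pd.DataFrame] = {}
    blup_cov: dict[str, np.ndarray] = {}
    for k, lab in enumerate(rand_labels):
        s = blk[k]
        u = bhat_std[s] * scale
        Bk = Binv[s, s] * s2
        if lab in boundary:
            u = np.zeros_like(u)
            Bk = np.zeros_like(Bk)
        blups[lab] = pd.DataFrame(
            {"level": rand_levels[k], "blup": u, "pev": np.diag(Bk)}
        )
        blup_cov[lab] = Bk

    # full criterion (with constant) on the original scale
    f_orig = f_std + (n - p) * np.log(s2) + (n - p) * np.log(2 * np.pi)
    loglik = -0.5 * f_orig

    theta_names = list(rand_labels) + [f"resid:{g}" for g in group_levels]

    def objective_original(theta_orig: np.ndarray) -> float:
        th = np.maximum(np.asarray(theta_orig, float) / s2, _VAR_FLOOR)
        f, _, _ = crit_grad(th, False, False)
        return f + (n - p) * np.log(s2) + (n - p) * np.log(2 * np.pi)

    return LmmFit(
        spec=spec,
        n_obs=n,
        varcomp=varcomp,
        residual_varcomp=resvar,
        boundary=boundary,
        converged=converged,
        n_iter=n_iter,
        reml_loglik=float(loglik),
        beta=beta,
        beta_cov=beta_cov,
        fixed_levels=fixed_levels,
        fixed_slices=fixed_slices,
        blup_tables=blups,
        rank_deficient=rank_flag,
        message=str(getattr(res, "message", "")),
        _blup_cov=blup_cov,
        _objective=objective_original,
        _theta=theta_hat * s2,
        theta_names=theta_names,
    )


def adjusted_means(fit: LmmFit, factor: str | Sequence[str]) -> list[AdjustedMean]:
    """Least-squares means of a fixed factor with standard errors.

    For each observed level: the BLUE of (intercept + level effect),
    averaging equally over the levels of every other fixed factor — the
    standard adjusted (marginal) mean under sum-to-zero coding.  Levels
    never observed are not part of the design and are therefore excluded.
    """
    lab = term_label(factor)
    if lab not in fit.fixed_levels:
        raise ValueError(f"{lab!r} is not a fixed factor of this fit")
    if fit.rank_deficient:
        warnings.warn(
            "fixed design was rank deficient; some means may be inestimable",
            stacklevel=2,
        )
    levels = fit.fixed_levels[lab]
    sl = fit.fixed_slices[lab]
    p = len(fit.beta)
    out = []
    L = len(levels)
    for j, lev in enumerate(levels):
        c = np.zeros(p)
        c[0] = 1.0
        if L >= 2:
            if j < L - 1:
                c[sl.start + j] = 1.0
            else:
                c[sl] = -1.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(max(c @ fit.beta_cov @ c, 0.0)))
        out.append(AdjustedMean(level=lev, estimate=est, se=se))
    return out


def blup_pev(fit: LmmFit, term: str | Sequence[str]):
    """BLUPs, prediction-error variances and the mean pairwise PEV of
    differences for one random term.

    Returns
    -------
    table : DataFrame with columns level, blup, pev
    vbar_delta : float
        Mean over all level pairs of Var(BLUP_i - BLUP_j), the quantity
        entering generalized (Cullis) repeatability.
    """
    lab = term_label(term)
    if lab not in fit.blup_tables:
        raise ValueError(f"{lab!r} is not a random term of this fit")
    table = fit.blup_tables[lab]
    B = fit._blup_cov[lab]
    q = len(table)
    if q < 2:
        return table, float("nan")
    t = float(np.trace(B))
    s = float(B.sum())
    vbar = 2.0 * (q * t - s) / (q * (q - 1))
    return table, vbar
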