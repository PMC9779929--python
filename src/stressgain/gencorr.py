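"""Genetic correlations between growing conditions and between traits.

Between conditions, hybrid adjusted means are modelled as

    y_ip = mu + G_i + E_p + e_ip,   G_i ~ N(0, sigma2_G),
    e_ip ~ N(0, sigma2_ep)  (one residual variance per condition),

with the environment (condition) effects fixed, and the genetic correlation
between conditions p and p' estimated as

    r(p, p') = sigma2_G / sqrt((sigma2_G + sigma2_ep)(sigma2_G + sigma2_ep')).

Standard errors come from a delta-method approximation using the observed
information of the REML criterion.

Between traits, a bivariate model with an unstructured 2x2 genetic
covariance is fitted to the per-hybrid adjusted means of the two traits.
With one mean per hybrid and trait, genetic and residual covariance are not
jointly identifiable, so the stage-1 standard errors are treated as known
residual variances (residual covariance zero) and only the genetic
covariance matrix is estimated, by REML over the per-hybrid 2x2 marginal
covariances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from . import reml

__all__ = ["CorrEstimate", "env_genetic_correlations",
           "bivariate_trait_correlation"]

_Z_CAP = 12.0  # atanh(r) cap; tanh(12) differs from 1 by ~1e-10


@dataclass
class CorrEstimate:
    """A genetic correlation between two conditions or two traits."""

    a: str
    b: str
    r: float
    se: float
    sigma2_G: float       # genetic variance (common, or of trait a)
    sigma2_ea: float      # residual (or genetic of trait b for trait pairs)
    sigma2_eb: float
    boundary: bool = False


def _observed_vc_cov(objective, theta, floor=1e-12):
    """Covariance of variance-component estimates from the observed
    information of the -2*logLik criterion (central differences)."""
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    h = np.maximum(1e-4 * np.abs(theta), 1e-6 * max(np.abs(theta).max(), 1.0))
    H = np.empty((k, k))
    f0 = objective(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                fpp = objective(np.maximum(theta + 2*ei, floor))
                fmm = objective(np.maximum(theta - 2*ei, floor))
                H[i, i] = (fpp - 2*f0 + fmm) / (4*h[i]**2)
            else:
                fpp = objective(np.maximum(theta + ei + ej, floor))
                fpm = objective(np.maximum(theta + ei - ej, floor))
                fmp = objective(np.maximum(theta - ei + ej, floor))
                fmm = objective(np.maximum(theta - ei - ej, floor))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4*h[i]*h[j])
    info = 0.5 * H  # information of the log-likelihood itself
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return cov


def _eq4(sg2, sa2, sb2):
    denom = np.sqrt((sg2 + sa2) * (sg2 + sb2))
    return sg2 / denom if denom > 0 else 0.0


def env_genetic_correlations(
    means: pd.DataFrame, *, min_shared: int = 10
) -> tuple[pd.DataFrame, list[CorrEstimate]]:
    """Pairwise genetic correlations between growing conditions.

    ``means`` is a stage-1 adjusted-means table with columns hybrid,
    condition, estimate (and optionally se; the model estimates its own
    per-condition residual variances).  Returns the symmetric correlation
    matrix (unit diagonal) and the per-pair estimates with delta-method
    standard errors.
    """
    conds = sorted(means["condition"].unique())
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions")
    for a, b in combinations(conds, 2):
        shared = (set(means.loc[means["condition"] == a, "hybrid"])
                  & set(means.loc[means["condition"] == b, "hybrid"]))
        if len(shared) < min_shared:
            raise ValueError(
                f"conditions {a} and {b} share only {len(shared)} hybrids "
                f"(< {min_shared})"
            )
    spec = reml.ModelSpec(
        response="estimate",
        fixed_terms=("condition",),
        random_terms=("hybrid",),
        residual_groups="condition",
        pool_small_groups=0,
    )
    fit = reml.fit_lmm(means, spec)
    sg2 = fit.varcomp["hybrid"]
    res = fit.residual_varcomp
    boundary = "hybrid" in fit.boundary or sg2 <= 0.0

    theta = np.asarray(fit._theta, dtype=float)
    cov = None
    if not boundary:
        cov = _observed_vc_cov(fit.objective, theta)
    names = fit.theta_names

    pairs: list[CorrEstimate] = []
    mat = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    for a, b in combinations(conds, 2):
        sa2, sb2 = res[a], res[b]
        if boundary:
            r, se = 0.0, float("nan")
        else:
            r = _eq4(sg2, sa2, sb2)
            idx = [names.index("hybrid"),
                   names.index(f"resid:{a}"), names.index(f"resid:{b}")]
            th = np.array([sg2, sa2, sb2])
            grad = np.zeros(3)
            h = np.maximum(1e-5 * th, 1e-8)
            for i in range(3):
                tp, tm = th.copy(), th.copy()
                tp[i] += h[i]
                tm[i] = max(tm[i] - h[i], 0.0)
                grad[i] = (_eq4(*tp) - _eq4(*tm)) / (tp[i] - tm[i])
            sub = cov[np.ix_(idx, idx)]
            var = float(grad @ sub @ grad)
            se = float(np.sqrt(var)) if var > 0 else float("nan")
        pairs.append(CorrEstimate(a=a, b=b, r=float(r), se=se,
                                  sigma2_G=float(sg2),
                                  sigma2_ea=float(sa2),
                                  sigma2_eb=float(sb2),
                                  boundary=boundary))
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat, pairs


def _bivariate_reml(y1, s1, y2, s2):
    """REML of the 2x2 genetic covariance from paired hybrid means with
    known error variances.  Returns (v1, v2, r, minus2loglik_fun, theta)."""
    y = np.column_stack([y1, y2])
    s2m = np.column_stack([s1**2, s2**2])
    n = len(y)

    def neg2loglik(params):
        v1, v2, c = params
        a = v1 + s2m[:, 0]
        b = v2 + s2m[:, 1]
        det = a * b - c**2
        if np.any(det <= 0) or v1 <= 0 or v2 <= 0:
            return np.inf
        # V_i^{-1} entries
        ia, ib, ic = b / det, a / det, -c / det
        # GLS mean per trait
        M = np.array([[ia.sum(), ic.sum()], [ic.sum(), ib.sum()]])
        rhs = np.array([(ia * y[:, 0] + ic * y[:, 1]).sum(),
                        (ic * y[:, 0] + ib * y[:, 1]).sum()])
        mu = np.linalg.solve(M, rhs)
        r1 = y[:, 0] - mu[0]
        r2 = y[:, 1] - mu[1]
        quad = (ia * r1**2 + 2 * ic * r1 * r2 + ib * r2**2).sum()
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        return float(np.log(det).sum() + quad + logdetM)

    v10 = max(np.var(y1, ddof=1) - s2m[:, 0].mean(), 1e-6 * np.var(y1, ddof=1))
    v20 = max(np.var(y2, ddof=1) - s2m[:, 1].mean(), 1e-6 * np.var(y2, ddof=1))
    r0 = np.clip(np.corrcoef(y1, y2)[0, 1], -0.95, 0.95)
    if not np.isfinite(r0):
        r0 = 0.0

    def unpack(phi):
        v1, v2 = np.exp(phi[0]), np.exp(phi[1])
        z = np.clip(phi[2], -_Z_CAP, _Z_CAP)
        return np.array([v1, v2, np.tanh(z) * np.sqrt(v1 * v2)])

    res = optimize.minimize(
        lambda phi: neg2loglik(unpack(phi)),
        np.array([np.log(v10), np.log(v20), np.arctanh(r0)]),
        method="Nelder-Mead",
        options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
    )
    theta = unpack(res.x)
    v1, v2, c = theta
    r = c / np.sqrt(v1 * v2)
    return v1, v2, float(r), neg2loglik, theta


def bivariate_trait_correlation(
    data: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    condition: str | None = None,
    *,
    level: str = "means",
    min_shared: int = 10,
) -> CorrEstimate:
    """Genetic correlation between two traits from a bivariate model.

    ``level='means'``: ``data`` is a long adjusted-means table with columns
    hybrid, trait, estimate, se.  ``level='plots'``: ``data`` is a plot
    table; per-trait adjusted means are computed first with the combined
    stage-1 model, then the bivariate genetic covariance is estimated.

    The correlation is clamped to [-1, 1] with a boundary flag when
    sampling noise pushes it outside; if either genetic variance collapses
    to zero the correlation is undefined (NaN).
    """
    if level == "plots":
        from .trend import stage1_means

        frames = []
        for tr in (trait_a, trait_b):
            m = stage1_means(data, condition, response=tr)
            m = m.rename(columns={"estimate": "estimate"})
            m["trait"] = tr
            frames.append(m[["hybrid", "trait", "estimate", "se"]])
        data = pd.concat(frames, ignore_index=True)
    elif level != "means":
        raise ValueError("level must be 'means' or 'plots'")

    wide = data.pivot(index="hybrid", columns="trait",
                      values=["estimate", "se"])
    for tr in (trait_a, trait_b):
        if ("estimate", tr) not in wide.columns:
            raise ValueError(f"no means for trait {tr!r}")
    wide = wide.dropna(
        subset=[("estimate", trait_a), ("estimate", trait_b)]
    )
    if len(wide) < min_shared:
        raise ValueError(
            f"only {len(wide)} hybrids share both traits (< {min_shared})"
        )
    y1 = wide[("estimate", trait_a)].to_numpy(float)
    y2 = wide[("estimate", trait_b)].to_numpy(float)
    s1 = wide[("se", trait_a)].to_numpy(float)
    s2 = wide[("se", trait_b)].to_numpy(float)

    v1, v2, r, neg2ll, theta = _bivariate_reml(y1, s1, y2, s2)

    tiny = 1e-8 * max(np.var(y1, ddof=1), np.var(y2, ddof=1), 1.0)
    if v1 < tiny or v2 < tiny:
        return CorrEstimate(a=trait_a, b=trait_b, r=float("nan"),
                            se=float("nan"), sigma2_G=float(v1),
                            sigma2_ea=float(v2), sigma2_eb=float("nan"),
                            boundary=True)

    boundary = abs(r) > 0.9999
    r_out = float(np.sign(r)) if boundary else float(r)
    se = float("nan")
    if not boundary:
        cov = _observed_vc_cov(neg2ll, theta)

        def r_of(th):
            return th[2] / np.sqrt(th[0] * th[1])

        grad = np.zeros(3)
        h = np.maximum(1e-5 * np.abs(theta), 1e-8)
        for i in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            grad[i] = (r_of(tp) - r_of(tm)) / (2 * h[i])
        var = float(grad @ cov @ grad)
        se = float(np.sqrt(var)) if var > 0 else float("nan")
    return CorrEstimate(a=trait_a, b=trait_b, r=r_out, se=se,
                        sigma2_G=float(v1), sigma2_ea=float(v2),
                        sigma2_eb=float("nan"), boundary=boundary)
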