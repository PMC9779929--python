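"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from the textbook definitions with
dense linear algebra (marginal covariance matrices, explicit GLS and
weighted normal equations) and shares no code with the package's
mixed-model-equation implementation.
"""

import numpy as np
import pandas as pd


def sum_to_zero_design(data: pd.DataFrame, factors) -> np.ndarray:
    """Intercept + sum-to-zero contrasts, built via dummy matrices."""
    n = len(data)
    cols = [np.ones((n, 1))]
    for f in factors:
        d = pd.get_dummies(data[f]).to_numpy(dtype=float)  # sorted levels
        L = d.shape[1]
        if L < 2:
            continue
        # drop the last level; rows at the last level become -1
        M = d[:, :-1] - d[:, [-1]]
        cols.append(M)
    return np.hstack(cols)


def indicator(data: pd.DataFrame, cols) -> np.ndarray:
    """Dense 0/1 design for the observed levels of a (joint) factor."""
    if isinstance(cols, str):
        cols = [cols]
    key = data[list(cols)].astype(str).agg("|".join, axis=1)
    return pd.get_dummies(key).to_numpy(dtype=float)


def marginal_covariance(data, random_terms, variances, resid_var_by_row):
    """V = sum_k sigma2_k Z_k Z_k' + diag(residual variances)."""
    n = len(data)
    V = np.diag(np.asarray(resid_var_by_row, dtype=float))
    for term, s2 in zip(random_terms, variances):
        Z = indicator(data, term)
        V += s2 * (Z @ Z.T)
    return V


def dense_reml_criterion(y, X, V):
    """-2 restricted log-likelihood from the marginal covariance."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    s1, ld_V = np.linalg.slogdet(V)
    s2, ld_X = np.linalg.slogdet(XtViX)
    assert s1 > 0 and s2 > 0
    return ld_V + ld_X + quad + (n - p) * np.log(2 * np.pi)


def gls_estimates(y, X, V):
    """GLS fixed-effect estimates and covariance at a known V."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    cov = np.linalg.inv(XtViX)
    beta = cov @ (X.T @ Vi @ y)
    return beta, cov


def wls_fit(y, x, w):
    """Weighted normal equations (X'WX)^-1 X'Wy with the usual estimated
    scale, returning (intercept, slope, slope_se).  The covariate is
    centred at its weighted mean for numerical stability (calendar years
    squared are badly conditioned); the intercept is shifted back."""
    xc = x - np.average(x, weights=w)
    X = np.column_stack([np.ones_like(xc), xc])
    Wm = np.diag(w)
    XtWX = X.T @ Wm @ X
    beta = np.linalg.solve(XtWX, X.T @ Wm @ y)
    r = y - X @ beta
    scale = float(r @ Wm @ r) / (len(y) - 2)
    cov = scale * np.linalg.inv(XtWX)
    intercept = beta[0] - beta[1] * np.average(x, weights=w)
    return intercept, beta[1], float(np.sqrt(cov[1, 1]))


def anova_oneway_components(y_by_group):
    """Method-of-moments variance components for a balanced one-way layout."""
    groups = [np.asarray(g, dtype=float) for g in y_by_group]
    n = len(groups[0])
    means = np.array([g.mean() for g in groups])
    msb = n * means.var(ddof=1)
    msw = float(np.mean([g.var(ddof=1) for g in groups]))
    return (msb - msw) / n, msw
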