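"""Trait-structure analysis: PCA on hybrid trait BLUPs and yield-on-PC1.

Principal components are extracted from the *correlation* matrix of the
per-hybrid trait BLUPs (so each trait enters on equal footing regardless of
units), trait-axis Pearson correlations identify which traits drive each
axis, and the hybrids' yield BLUPs are regressed on their PC1 scores to
test whether the leading axis of trait variation tracks yield.

Eigenvector signs are arbitrary; each loading vector is oriented so that
its largest-magnitude entry is positive, making directional statements
reproducible.  Hybrids with any missing trait are dropped (complete-case);
constant trait columns are dropped with a warning before the PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import reml

__all__ = ["PcaResult", "RegressionResult", "hybrid_blups", "pca_blups",
           "trait_pc_correlations", "yield_on_pc1"]


@dataclass
class PcaResult:
    """Correlation-matrix PCA of a hybrids-by-traits BLUP matrix."""

    loadings: pd.DataFrame      # traits x axes (eigenvectors, oriented)
    scores: pd.DataFrame        # hybrids x axes (standardized data x vecs)
    eigenvalues: np.ndarray
    proportions: np.ndarray     # proportion of total variance per axis
    dropped_traits: list


@dataclass
class RegressionResult:
    """Simple OLS summary for the yield-on-PC1 regression."""

    slope: float
    intercept: float
    slope_se: float
    r2: float
    p: float
    n: int


def hybrid_blups(
    plots: pd.DataFrame,
    traits,
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-hybrid BLUPs for each trait under one condition.

    Each trait is fitted with hybrids random, years fixed (when >1 year),
    a random replicate-within-environment term, and a single residual
    variance — a light model adequate for building the BLUP matrix.
    """
    df = plots if condition is None else plots.loc[
        plots["condition"] == condition
    ]
    conds = df["condition"].unique()
    if len(conds) != 1:
        raise ValueError("hybrid_blups expects a single condition")
    out = {}
    for tr in traits:
        sub = df.loc[df[tr].notna()]
        if sub.empty:
            warnings.warn(f"trait {tr!r} has no data; skipped", stacklevel=2)
            continue
        fixed = ("year",) if sub["year"].nunique() > 1 else ()
        spec = reml.ModelSpec(
            response=tr,
            fixed_terms=fixed,
            random_terms=("hybrid", "year:location:replicate"),
            residual_groups=None,
        )
        fit = reml.fit_lmm(sub, spec)
        tab = fit.blup_tables["hybrid"]
        out[tr] = pd.Series(tab["blup"].to_numpy(), index=tab["level"])
    m = pd.DataFrame(out)
    m.index.name = "hybrid"
    return m


def pca_blups(matrix: pd.DataFrame) -> PcaResult:
    """PCA of the trait correlation matrix.

    Requires >= 3 hybrids (rows) and >= 2 non-constant traits (columns)
    after complete-case filtering.
    """
    m = matrix.dropna(axis=0, how="any")
    if len(m) < 3:
        raise ValueError("PCA needs >= 3 hybrids with complete traits")
    sds = m.std(ddof=1)
    dropped = list(sds.index[(sds == 0) | sds.isna()])
    if dropped:
        warnings.warn(
            f"dropping constant trait columns from PCA: {dropped}",
            stacklevel=2,
        )
        m = m.drop(columns=dropped)
    if m.shape[1] < 2:
        raise ValueError("PCA needs >= 2 non-constant traits")

    Z = (m - m.mean()) / m.std(ddof=1)
    R = np.asarray(Z.T @ Z) / (len(m) - 1)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # orient: largest-magnitude loading of each axis positive
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    axes = [f"PC{j + 1}" for j in range(len(vals))]
    loadings = pd.DataFrame(vecs, index=m.columns, columns=axes)
    scores = pd.DataFrame(np.asarray(Z) @ vecs, index=m.index, columns=axes)
    proportions = vals / vals.sum()
    return PcaResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=vals,
        proportions=proportions,
        dropped_traits=dropped,
    )


def trait_pc_correlations(
    matrix: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations between trait BLUPs and PC axis scores.

    For correlation-matrix PCA these equal loading * sqrt(eigenvalue);
    computing them directly from the data provides an internal consistency
    route.
    """
    m = matrix.loc[scores.index]
    out = pd.DataFrame(index=m.columns, columns=scores.columns, dtype=float)
    for tr in m.columns:
        x = m[tr].to_numpy(float)
        for ax in scores.columns:
            s = scores[ax].to_numpy(float)
            sx, ss = np.std(x), np.std(s)
            out.loc[tr, ax] = (
                np.corrcoef(x, s)[0, 1] if sx > 0 and ss > 0 else np.nan
            )
    return out


def yield_on_pc1(yield_blups, pc1_scores) -> RegressionResult:
    """OLS of yield BLUPs on PC1 scores (two-sided slope p on n-2 df)."""
    y = np.asarray(yield_blups, dtype=float)
    x = np.asarray(pc1_scores, dtype=float)
    if len(y) != len(x):
        raise ValueError("yield and scores differ in length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if len(y) < 3:
        raise ValueError("regression needs >= 3 hybrids")
    if np.std(x) == 0:
        raise ValueError("degenerate design: PC1 scores are constant")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        r2=float(res.rsquared),
        p=float(res.pvalues[1]),
        n=int(len(y)),
    )
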