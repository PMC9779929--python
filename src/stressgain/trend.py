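"""Two-stage genetic-trend estimation per growing condition.

Stage 1 fits a combined mixed model over the condition's retained
environments with hybrids and years *fixed* (so the genetic trend is not
shrunk), replicates, blocks, hybrid-by-year and location-within-year
effects random, and a separate residual variance per environment:

    multi-location:  y = mu + G_i + Y_k + R_rjk + B_brjk + GY_ik + S_jk + e
    single-location: y = mu + G_i + Y_k + R_rk  + B_brk  + GY_ik        + e

(the location terms and j indices drop for the single-station managed
conditions, where the residual is grouped by year instead of
location-year).  Stage 2 regresses the hybrid adjusted means on year of
first testing, weighting by the inverse squared standard errors, and
expresses the slope as a percentage of the predicted mean of the first
testing year:

    percent gain = 100 * slope / (intercept + slope * first_year).

Check entries (LOCAL and the commercial classes) are excluded from stage 2
by default since their year of origin predates the program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import reml
from .io import with_environment

__all__ = ["GainEstimate", "DegenerateDesignError", "stage1_means",
           "stage2_trend", "percent_gain", "genetic_gain_pipeline"]


class DegenerateDesignError(ValueError):
    """Stage-2 design cannot identify a trend."""


@dataclass
class GainEstimate:
    """Stage-2 weighted-regression trend for one growing condition."""

    condition: str
    slope: float          # kg/ha per year
    slope_se: float
    t: float
    p: float              # two-sided, n-2 df
    intercept: float
    first_year: int
    first_year_baseline: float
    percent_gain: float   # % per year; NaN when the baseline is <= 0
    n_hybrids: int


def stage1_means(
    plots: pd.DataFrame,
    condition: str | None = None,
    kept_environments=None,
    *,
    response: str = "grain_yield",
) -> pd.DataFrame:
    """Hybrid adjusted means (BLUEs) from the combined per-condition model.

    Parameters
    ----------
    plots
        Plot table (one condition, or pass ``condition`` to subset).
    kept_environments
        Iterable of 'condition|location|year' keys retained by the
        repeatability filter; ``None`` keeps everything.
    response
        Trait column to analyse (grain yield by default).

    Returns a table with hybrid, hybrid_class, condition, estimate, se,
    weight, first_year (first testing year over the condition's full
    data), years_tested and n_plots.
    """
    df = with_environment(plots)
    if condition is not None:
        df = df.loc[df["condition"] == condition]
    conds = df["condition"].unique()
    if len(conds) != 1:
        raise ValueError("stage1_means expects a single condition")
    cond = conds[0]
    df = df.loc[df[response].notna()]

    # first testing year / tenure from the full (pre-filter) condition data
    first_year = df.groupby("hybrid")["year"].min()
    years_tested = df.groupby("hybrid")["year"].nunique()
    classes = df.groupby("hybrid")["hybrid_class"].first()

    if kept_environments is not None:
        kept = set(kept_environments)
        sub = df.loc[df["environment"].isin(kept)]
        lost = set(df["hybrid"]) - set(sub["hybrid"])
        if lost:
            warnings.warn(
                f"{len(lost)} hybrids observed only in discarded "
                f"environments were dropped: {sorted(lost)[:5]}...",
                stacklevel=2,
            )
        df = sub
    if df["year"].nunique() < 2:
        raise ValueError("stage 1 needs >= 2 years of retained data")

    multi_location = df["location"].nunique() > 1
    random_terms = [
        "year:location:replicate",
        "year:location:replicate:block",
        "hybrid:year",
    ]
    if multi_location:
        random_terms.append("location:year")
        residual_by = "environment"
    else:
        residual_by = "year"
    spec = reml.ModelSpec(
        response=response,
        fixed_terms=("hybrid", "year"),
        random_terms=tuple(random_terms),
        residual_groups=residual_by,
    )
    fit = reml.fit_lmm(df, spec)
    means = reml.adjusted_means(fit, "hybrid")
    out = pd.DataFrame(
        {
            "hybrid": [m.level for m in means],
            "estimate": [m.estimate for m in means],
            "se": [m.se for m in means],
        }
    )
    out["condition"] = cond
    out["hybrid_class"] = out["hybrid"].map(classes)
    out["first_year"] = out["hybrid"].map(first_year).astype(int)
    out["years_tested"] = out["hybrid"].map(years_tested).astype(int)
    out["n_plots"] = out["hybrid"].map(df.groupby("hybrid").size()).astype(int)
    # noise-free data yields (numerically) zero SEs; floor keeps the
    # stage-2 weights finite without affecting any stochastic fit
    out["weight"] = 1.0 / np.maximum(out["se"], 1e-8) ** 2
    out.attrs["fit"] = fit
    return out[["hybrid", "hybrid_class", "condition", "estimate", "se",
                "weight", "first_year", "years_tested", "n_plots"]]


def percent_gain(slope: float, intercept: float, first_year: float) -> float:
    """Annual gain as a percentage of the predicted first-year mean.

    100 * slope / (intercept + slope * first_year); the baseline must be
    positive for the percentage to be meaningful — otherwise NaN is
    returned (flagged undefined).
    """
    baseline = intercept + slope * first_year
    if baseline <= 0:
        return float("nan")
    return 100.0 * slope / baseline


def stage2_trend(
    means: pd.DataFrame,
    *,
    include_classes: tuple | None = ("DTSTR",),
) -> GainEstimate:
    """Weighted regression of adjusted means on year of first testing.

    Weights are 1/se^2; inference on n-2 degrees of freedom.  Check
    entries are excluded by default (``include_classes=None`` pools all
    classes).
    """
    df = means
    if include_classes is not None:
        df = df.loc[df["hybrid_class"].isin(include_classes)]
    df = df.loc[df["estimate"].notna() & df["se"].notna()]
    if len(df) < 3:
        raise DegenerateDesignError("stage 2 needs >= 3 hybrids")
    if df["first_year"].nunique() < 2:
        raise DegenerateDesignError(
            "all first testing years identical: no trend estimable"
        )
    X = sm.add_constant(df["first_year"].to_numpy(dtype=float))
    model = sm.WLS(df["estimate"].to_numpy(dtype=float), X,
                   weights=df["weight"].to_numpy(dtype=float))
    res = model.fit()
    intercept, slope = res.params
    fy = int(df["first_year"].min())
    baseline = intercept + slope * fy
    cond = df["condition"].iloc[0] if "condition" in df else ""
    return GainEstimate(
        condition=cond,
        slope=float(slope),
        slope_se=float(res.bse[1]),
        t=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        intercept=float(intercept),
        first_year=fy,
        first_year_baseline=float(baseline),
        percent_gain=percent_gain(slope, intercept, fy),
        n_hybrids=int(len(df)),
    )


def genetic_gain_pipeline(
    plots: pd.DataFrame,
    *,
    threshold: float = 0.2,
    include_classes: tuple | None = ("DTSTR",),
    response: str = "grain_yield",
):
    """QC -> stage 1 -> stage 2 for every condition in the table.

    Returns (qc table, stage-1 means over all conditions, gains table).
    """
    from .qc import filter_trials, qc_environments

    qc = qc_environments(plots)
    kept, _ = filter_trials(qc, threshold)
    means_all, gains = [], []
    for cond in plots["condition"].unique():
        kept_envs = kept.loc[kept["condition"] == cond, "environment"]
        means = stage1_means(
            plots, cond, kept_environments=kept_envs, response=response
        )
        means_all.append(means)
        gains.append(stage2_trend(means, include_classes=include_classes))
    means_df = pd.concat(means_all, ignore_index=True)
    gains_df = pd.DataFrame([g.__dict__ for g in gains])
    return qc, means_df, gains_df
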