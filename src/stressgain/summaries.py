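"""Check-relative performance and stress-reduction descriptives.

Mirrors the comparisons breeders report from regional trials: the mean
adjusted yield of a (possibly top-k, tenure-filtered) group of test hybrids
relative to a check group, and the percent yield reduction a stress
treatment imposed relative to its non-stress control.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GroupComparison", "ComparisonError",
           "group_relative_yield", "stress_reduction"]


class ComparisonError(ValueError):
    """A comparison group is empty or its denominator non-positive."""


@dataclass
class GroupComparison:
    """Relative yield of group a over group b, from adjusted means."""

    condition: str
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    relative_gain: float  # 100 * (mean_a / mean_b - 1)


def _select(means: pd.DataFrame, classes, min_years: int, top_k):
    sub = means.loc[means["hybrid_class"].isin(tuple(classes))]
    if min_years and "years_tested" in sub:
        sub = sub.loc[sub["years_tested"] >= min_years]
    if top_k is not None:
        # rank by adjusted mean, ties broken by hybrid id for determinism
        sub = sub.sort_values(
            ["estimate", "hybrid"], ascending=[False, True]
        ).head(top_k)
    return sub


def group_relative_yield(
    means: pd.DataFrame,
    classes_a,
    classes_b,
    *,
    min_years: int = 0,
    top_k_a: int | None = None,
    condition: str | None = None,
) -> GroupComparison:
    """Percent yield advantage of one hybrid-class group over another.

    Both groups are restricted to entries tested at least ``min_years``
    years; group a may additionally be truncated to its best ``top_k_a``
    entries by adjusted mean.  Group means are simple (unweighted) means
    of the adjusted means.
    """
    df = means if condition is None else means.loc[
        means["condition"] == condition
    ]
    a = _select(df, classes_a, min_years, top_k_a)
    b = _select(df, classes_b, min_years, None)
    if a.empty or b.empty:
        raise ComparisonError(
            f"empty comparison group (a: {len(a)}, b: {len(b)})"
        )
    mean_a = float(a["estimate"].mean())
    mean_b = float(b["estimate"].mean())
    if mean_b <= 0:
        raise ComparisonError("reference group mean must be > 0")
    cond = df["condition"].iloc[0] if "condition" in df else ""
    return GroupComparison(
        condition=str(cond),
        label_a="+".join(classes_a) + (f" top{top_k_a}" if top_k_a else ""),
        label_b="+".join(classes_b),
        mean_a=mean_a,
        mean_b=mean_b,
        n_a=int(len(a)),
        n_b=int(len(b)),
        relative_gain=100.0 * (mean_a / mean_b - 1.0),
    )


def stress_reduction(mean_stress: float, mean_nonstress: float) -> float:
    """Percent yield reduction under stress: 100 * (1 - stress/nonstress).

    At most 100 (total loss); negative when the stress mean exceeds the
    control.  The non-stress denominator must be positive.
    """
    if mean_nonstress <= 0:
        raise ComparisonError("non-stress mean must be > 0")
    return 100.0 * (1.0 - mean_stress / mean_nonstress)
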