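"""Per-trial repeatability and the 0.2 filter.

Each location-year environment is analysed on its own with hybrids random
(replicates and incomplete blocks random where present) and generalized
repeatability is computed on the BLUP-difference basis,

    h2 = 1 - vbar_Delta / (2 * sigma2_g),

where vbar_Delta is the mean pairwise prediction-error variance of hybrid
BLUP differences.  This form is well defined for unbalanced trials where
not every hybrid reaches every replicate; for balanced designs it is close
to the classical sigma2_g / (sigma2_g + sigma2_e / r).  Trials with
repeatability below the threshold (default 0.2, strict inequality) are
discarded from the genetic-trend stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import reml
from .io import with_environment

__all__ = ["TrialQC", "QcError", "trial_repeatability",
           "qc_environments", "filter_trials", "DEFAULT_H2_THRESHOLD"]

DEFAULT_H2_THRESHOLD = 0.2


class QcError(ValueError):
    """The trial cannot be QC'd (e.g. a single replicate)."""


@dataclass
class TrialQC:
    """Repeatability summary of one trial (environment)."""

    condition: str
    location: str
    year: int
    environment: str
    h2: float
    sigma2_g: float
    sigma2_e: float
    n_hybrids: int
    n_plots: int
    kept: bool = True
    converged: bool = True


def trial_repeatability(
    plots: pd.DataFrame, *, include_reps: bool = True,
    include_blocks: bool = True, start: dict | None = None
) -> TrialQC:
    """Generalized (Cullis) repeatability of a single trial.

    ``plots`` must contain exactly one environment with >= 2 replicates;
    hybrids are fitted random alongside replicate (and block-in-replicate
    when present and informative).  ``include_reps=False`` drops the
    design terms and analyses the trial one-way (useful for data without
    a real replicate structure).
    """
    env = with_environment(plots)
    keys = env["environment"].unique()
    if len(keys) != 1:
        raise QcError(f"expected one environment, got {len(keys)}")
    sub = env.loc[env["grain_yield"].notna()]
    if sub["replicate"].nunique() < 2:
        raise QcError("single replicate: within-trial error not estimable")

    random_terms = ["hybrid"]
    if include_reps:
        random_terms.append("replicate")
        if include_blocks and "block" in sub.columns:
            if sub.groupby("replicate")["block"].nunique().max() > 1:
                random_terms.append("replicate:block")
    spec = reml.ModelSpec(
        response="grain_yield",
        random_terms=tuple(random_terms),
        residual_groups=None,
    )
    fit = reml.fit_lmm(sub, spec, start=start)
    sigma2_g = fit.varcomp["hybrid"]
    sigma2_e = fit.residual_varcomp["all"]
    if sigma2_g <= 0.0:
        h2 = 0.0  # boundary convention: the BLUP-difference form is 0/0
    else:
        _, vbar = reml.blup_pev(fit, "hybrid")
        h2 = 1.0 - vbar / (2.0 * sigma2_g)
        h2 = min(max(h2, 0.0), 1.0)
    row = sub.iloc[0]
    qc = TrialQC(
        condition=row["condition"],
        location=row["location"],
        year=int(row["year"]),
        environment=keys[0],
        h2=float(h2),
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        n_hybrids=int(sub["hybrid"].nunique()),
        n_plots=int(len(sub)),
        converged=fit.converged,
    )
    qc._fit = fit
    return qc


def qc_environments(
    plots: pd.DataFrame, *, include_blocks: bool = True
) -> pd.DataFrame:
    """Repeatability table over every environment in the plot table.

    Consecutive trials of a condition warm-start each other's REML fit
    (same optimum, fewer iterations)."""
    env = with_environment(plots)
    rows = []
    starts: dict[str, dict] = {}
    for _, sub in env.groupby("environment", sort=True):
        cond = sub["condition"].iloc[0]
        qc = trial_repeatability(
            sub, include_blocks=include_blocks, start=starts.get(cond)
        )
        fit = qc._fit
        if fit.converged and not fit.boundary:
            starts[cond] = dict(fit.varcomp) | {
                "resid:all": fit.residual_varcomp["all"]
            }
        rows.append(qc)
    return pd.DataFrame(
        [{k: v for k, v in r.__dict__.items() if not k.startswith("_")}
         for r in rows]
    )


def filter_trials(
    qc: pd.DataFrame, threshold: float = DEFAULT_H2_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the QC table by the repeatability filter.

    Strict inequality discards: a trial with h2 exactly at the threshold
    is kept.  Returns (kept, discarded), each with the ``kept`` flag set.
    """
    qc = qc.copy()
    qc["kept"] = qc["h2"] >= threshold
    kept = qc.loc[qc["kept"]].reset_index(drop=True)
    discarded = qc.loc[~qc["kept"]].reset_index(drop=True)
    return kept, discarded
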