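"""Seeded simulation studies over the full pipeline.

These are the parameter-recovery experiments the package uses to validate
itself: repeated synthetic programs with known truth pushed through the
two-stage analysis (and the repeatability filter), summarised as bias,
confidence-interval coverage, type-I error, correlation recovery and
filter accuracy.  The same routines back the test suite, the acceptance
script and the analysis drivers.

Problem sizes are chosen to keep hundreds of replicates affordable: the
trend study uses the single-station managed-drought design (8 years, 3
replicates, one location) with a reduced entry list (28 test hybrids,
~10 per trial); the filter study uses trials large enough (420 entries)
for the 0.2 threshold to separate cleanly, since the null spread of
per-trial repeatability is ~sqrt(2/(k-1)) for k entries.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .gencorr import env_genetic_correlations
from .qc import filter_trials, qc_environments
from .simulate import (
    ProgramConfig,
    TruthRecord,
    build_program,
    simulate_adjusted_means,
)
from .trend import stage1_means, stage2_trend

__all__ = [
    "trend_recovery_config",
    "trend_recovery_study",
    "filter_recovery_config",
    "filter_recovery_study",
    "corr_recovery_study",
]

#: entry list of the compact trend-recovery program (tenure -> count)
_RECOVERY_TENURE = {1: 10, 2: 6, 3: 4, 4: 3, 5: 2, 6: 1, 7: 1, 8: 1}


def trend_recovery_config(trend: float) -> ProgramConfig:
    """Managed-drought-style design (8 years, 1 location, 3 reps) with a
    known planted trend and no low-repeatability environments."""
    truth = TruthRecord(
        trend_per_condition={"MDS": float(trend)},
        low_h2_fraction={},
        # recovery tests the estimator under the generating model; the
        # zero-truncation realism feature would attenuate planted trends
        clip_negative_yields=False,
    )
    return ProgramConfig(
        conditions=("MDS",),
        tenure_distribution={"DTSTR": dict(_RECOVERY_TENURE)},
        truth=truth,
    )


def trend_recovery_study(
    trend: float, n_rep: int, seed0: int, *, level: float = 0.95
) -> pd.DataFrame:
    """Run ``n_rep`` seeded programs with a planted trend through both
    stages; one row per replicate with the slope estimate, its SE, the
    two-sided p-value and whether the CI covered the truth."""
    cfg = trend_recovery_config(trend)
    rows = []
    for i in range(n_rep):
        plots, _ = build_program(cfg, seed=seed0 + i)
        means = stage1_means(plots, "MDS")
        g = stage2_trend(means)
        tcrit = stats.t.ppf(0.5 + level / 2, g.n_hybrids - 2)
        covered = abs(g.slope - trend) <= tcrit * g.slope_se
        rows.append(
            dict(seed=seed0 + i, trend=trend, slope=g.slope,
                 se=g.slope_se, p=g.p, covered=bool(covered),
                 percent_gain=g.percent_gain)
        )
    return pd.DataFrame(rows)


def filter_recovery_config(
    n_environments: int = 50, low_fraction: float = 0.2,
    entries: int = 420,
) -> ProgramConfig:
    """MET-style program with a planted fraction of no-signal environments
    and trials large enough for exact filter recovery."""
    per_year = n_environments // 8
    extra = n_environments - per_year * 8
    locs = tuple(
        per_year + (1 if i < extra else 0) for i in range(8)
    )
    truth = TruthRecord(low_h2_fraction={"MET": low_fraction})
    # 3 replicates: with r reps and k entries the null sd of sigma2_g is
    # ~ sqrt(2(1/(k-1) + 1/(k(r-1)))) sigma_e^2 / r, so 2-rep trials
    # nearly double the false-keep rate of no-signal environments
    return ProgramConfig(
        conditions=("MET",),
        reps_per_condition={"MET": 3},
        met_locations_per_year=locs,
        tenure_distribution={"DTSTR": {8: entries}},
        block_size=10**6,  # one block per replicate: trials are unblocked
        truth=truth,
    )


def filter_recovery_study(
    n_rep: int, seed0: int, *, threshold: float = 0.2, **config_kw
) -> pd.DataFrame:
    """Repeat the 10-of-50 planted-environment filter experiment; one row
    per replicate recording whether the discarded set exactly equals the
    planted no-signal set."""
    cfg = filter_recovery_config(**config_kw)
    rows = []
    for i in range(n_rep):
        plots, truth = build_program(cfg, seed=seed0 + i)
        qc = qc_environments(plots)
        _, discarded = filter_trials(qc, threshold)
        planted = set(
            truth.environments.loc[truth.environments.low_h2, "environment"]
        )
        got = set(discarded.environment)
        rows.append(
            dict(seed=seed0 + i, n_planted=len(planted),
                 n_discarded=len(got), exact=got == planted,
                 missed=len(planted - got), spurious=len(got - planted))
        )
    return pd.DataFrame(rows)


def corr_recovery_study(
    n_rep: int, seed0: int, *, r_g: float = 0.5, n_hybrids: int = 150
) -> pd.DataFrame:
    """Between-condition correlation recovery from generator-truth
    adjusted means with known genetic correlation."""
    rows = []
    for i in range(n_rep):
        means = simulate_adjusted_means(
            n_hybrids, r_g=r_g, seed=seed0 + i
        )
        _, pairs = env_genetic_correlations(means)
        rows.append(dict(seed=seed0 + i, r=pairs[0].r, se=pairs[0].se))
    return pd.DataFrame(rows)
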