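"""Synthetic regional hybrid-trial program with known truth.

Emulates an eight-year West-African maize testing program in which elite
drought-tolerant / Striga-resistant (DTSTR) three-way hybrids are evaluated
against commercial and local checks under five growing conditions:

* ``MDS`` / ``WW`` — managed drought stress / well-watered control, one
  station, three replicates per trial;
* ``STRIN`` / ``STRNO`` — artificial *Striga hermonthica* infestation and
  its non-infested control, two locations, two replicates;
* ``MET`` — rainfed multi-environment trials at many collaborator sites,
  three replicates.

New hybrids enter every year and the worst are removed, so each entry has a
testing *tenure*; the default tenure tables reproduce the real program's
entry structure (112 DTSTR entries of which 42 were tested one year, ...,
3 for all eight years; 30 commercial checks; one local check) and a default
MET footprint of 174 location-year environments over eight years.

Every plot value is built from known components

    y = mu_c + s_env * (class offset + trend_c * first_year + g_ic + gy_ick)
        + year + location-in-year + replicate + block + N(0, sigma2_e(env))

so each downstream stage (repeatability filter, combined mixed model,
trend regression, genetic correlations) is testable by parameter recovery.
The genetic deviations g_ic are equicorrelated across conditions at a
configurable correlation, and secondary traits are linear in the yield
genetic value at configurable genetic correlations.  A configurable
fraction of environments is generated with near-zero genetic signal
(``s_env`` << 1) to exercise the repeatability filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "HYBRID_CLASSES",
    "TraitModel",
    "TruthRecord",
    "ProgramConfig",
    "ProgramTruth",
    "ConfigError",
    "build_program",
    "tenure_summary",
    "simulate_adjusted_means",
]

CONDITIONS = ("MDS", "WW", "STRIN", "STRNO", "MET")
HYBRID_CLASSES = ("DTSTR", "STRCOM", "CONCOM", "LOCAL")

# printed entry structure of the real program: tenure (years tested) -> count
DEFAULT_TENURE = {
    "DTSTR": {1: 42, 2: 26, 3: 15, 4: 12, 5: 6, 6: 3, 7: 5, 8: 3},
    # of the 30 commercial checks, one was common to all 8 years and one to
    # the 5-7 year group (the two Striga-resistant commercial hybrids)
    "STRCOM": {6: 1, 8: 1},
    "CONCOM": {1: 12, 2: 8, 3: 2, 4: 3, 5: 2, 7: 1},
    "LOCAL": {8: 1},
}

#: 174 rainfed MET environments over the 8 program years
DEFAULT_MET_LOCATIONS = (22, 22, 22, 22, 22, 22, 21, 21)


class ConfigError(ValueError):
    """Inconsistent program configuration."""


@dataclass(frozen=True)
class TraitModel:
    """Generating model of a secondary trait.

    Gaussian traits ("continuous", "days", "score"): hybrid genetic value
    = mean + r_g * genetic_sd * a_ic + sqrt(1-r_g^2) * genetic_sd * eta_i,
    where a_ic is the standardized yield genetic deviation, so the genetic
    correlation with yield is r_g by construction.  "score" traits are
    rounded and clipped to the 1-9 rating scale, "days" are rounded.
    "count" traits are Poisson with log-mean log(mean) + r_g * a_ic +
    noise (r_g acts as a log-scale slope).
    """

    name: str
    kind: str = "continuous"  # continuous | days | score | count
    mean: float = 0.0
    genetic_sd: float = 1.0
    r_g: float = 0.0
    noise_sd: float = 1.0
    conditions: tuple = CONDITIONS

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.kind not in ("continuous", "days", "score", "count"):
            raise ConfigError(f"unknown trait kind {self.kind!r}")
        if abs(self.r_g) > 1:
            raise ConfigError(f"|r_g| > 1 for trait {self.name}")


def default_trait_models() -> tuple[TraitModel, ...]:
    """Secondary traits with the qualitative genetic structure seen under
    drought and Striga stress: yield genetically tied negatively to
    flowering dates, ASI, ear aspect and Striga damage/emergence, and
    positively to plant stature and ears per plant."""
    return (
        TraitModel("days_anthesis", "days", 60.0, 1.8, -0.40, 1.2),
        TraitModel("asi", "days", 2.5, 1.0, -0.50, 1.0),
        TraitModel("plant_height", "continuous", 170.0, 10.0, 0.50, 8.0),
        TraitModel("ear_height", "continuous", 85.0, 7.0, 0.45, 6.0),
        TraitModel("ears_per_plant", "continuous", 0.90, 0.08, 0.50, 0.10),
        TraitModel("ear_aspect", "score", 5.0, 0.9, -0.50, 0.9),
        TraitModel("striga_damage_8wk", "score", 4.0, 1.0, -0.60, 0.9,
                   conditions=("STRIN",)),
        TraitModel("striga_damage_10wk", "score", 5.0, 1.1, -0.60, 0.9,
                   conditions=("STRIN",)),
        TraitModel("striga_count_8wk", "count", 12.0, 1.0, -0.50, 0.30,
                   conditions=("STRIN",)),
        TraitModel("striga_count_10wk", "count", 20.0, 1.0, -0.50, 0.30,
                   conditions=("STRIN",)),
    )


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters (the truth downstream stages must recover).

    All yield variances in kg^2 ha^-2, trends in kg ha^-1 yr^-1.  The
    default trends are the annual gains the program realized per growing
    condition; variance defaults put per-trial repeatabilities in the
    0.5-0.9 range typical of these trials.
    """

    trend_per_condition: dict = field(default_factory=lambda: {
        "MDS": 11.89, "WW": 62.65, "STRIN": 86.60,
        "STRNO": 102.44, "MET": 53.11,
    })
    #: classes whose genetic value carries the trend (checks are static)
    trend_classes: tuple = ("DTSTR",)
    sigma2_G: float = 200_000.0
    #: common pairwise genetic correlation of hybrid merit across conditions
    condition_genetic_corr: float = 0.6
    sigma2_GY: float = 60_000.0
    sigma2_S: float = 400_000.0
    sigma2_Y: float = 150_000.0
    sigma2_R: float = 20_000.0
    sigma2_B: float = 15_000.0
    residual_variance_per_condition: dict = field(default_factory=lambda: {
        "MDS": 550_000.0, "WW": 440_000.0, "STRIN": 450_000.0,
        "STRNO": 450_000.0, "MET": 680_000.0,
    })
    #: lognormal sd of the per-environment residual-variance jitter
    residual_lognorm_sd: float = 0.25
    condition_mean: dict = field(default_factory=lambda: {
        "MDS": 1900.0, "WW": 4400.0, "STRIN": 3900.0,
        "STRNO": 4500.0, "MET": 5600.0,
    })
    class_offset: dict = field(default_factory=lambda: {
        "DTSTR": 0.0, "STRCOM": -500.0, "CONCOM": -350.0, "LOCAL": -1500.0,
    })
    #: fraction of a condition's environments generated with near-zero
    #: genetic signal (the trials the 0.2 repeatability filter removes);
    #: defaults reproduce the 40/174 MET and 2/16 STRNO discard counts
    low_h2_fraction: dict = field(default_factory=lambda: {
        "MET": 40 / 174, "STRNO": 2 / 16,
    })
    low_h2_scale: float = 0.05
    #: truncate negative plot yields at zero (physical realism; adds a
    #: small attenuation of planted trends under severe stress means)
    clip_negative_yields: bool = True
    trait_models: tuple = field(default_factory=default_trait_models)
    rng_seed: int = 20120

    def validate(self):
        for name in ("sigma2_G", "sigma2_GY", "sigma2_S", "sigma2_Y",
                     "sigma2_R", "sigma2_B"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for c, v in self.residual_variance_per_condition.items():
            if v < 0:
                raise ConfigError(f"residual variance for {c} must be >= 0")
        if not 0 <= abs(self.condition_genetic_corr) <= 1:
            raise ConfigError("|condition_genetic_corr| must be <= 1")
        if self.condition_genetic_corr < 0:
            raise ConfigError(
                "equicorrelated genetic deviations require corr >= 0"
            )
        for c, f in self.low_h2_fraction.items():
            if not 0 <= f <= 1:
                raise ConfigError(f"low_h2_fraction[{c}] must be in [0,1]")
        if not 0 <= self.low_h2_scale <= 1:
            raise ConfigError("low_h2_scale must be in [0,1]")


@dataclass(frozen=True)
class ProgramConfig:
    """Design of the synthetic testing program."""

    n_years: int = 8
    start_year: int = 2012
    conditions: tuple = CONDITIONS
    reps_per_condition: dict = field(default_factory=lambda: {
        "MDS": 3, "WW": 3, "STRIN": 2, "STRNO": 2, "MET": 3,
    })
    #: fixed station(s) for the managed conditions
    locations_per_condition: dict = field(default_factory=lambda: {
        "MDS": ("IKENNE",), "WW": ("IKENNE",),
        "STRIN": ("ABUJA", "MOKWA"), "STRNO": ("ABUJA", "MOKWA"),
    })
    #: rainfed MET sites per year (new names each year: location-years)
    met_locations_per_year: tuple = DEFAULT_MET_LOCATIONS
    tenure_distribution: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TENURE.items()}
    )
    block_size: int = 6
    truth: TruthRecord = field(default_factory=TruthRecord)

    @property
    def entry_classes(self) -> dict:
        """Total entries per hybrid class (from the tenure table)."""
        return {cls: sum(d.values())
                for cls, d in self.tenure_distribution.items()}

    def validate(self):
        if self.n_years < 2:
            raise ConfigError("n_years must be >= 2 (a trend needs >= 2 "
                              "distinct first-testing years)")
        for cls, dist in self.tenure_distribution.items():
            if cls not in HYBRID_CLASSES:
                raise ConfigError(f"unknown hybrid class {cls!r}")
            for t, cnt in dist.items():
                if t < 1 or cnt < 0:
                    raise ConfigError(f"bad tenure entry {t}:{cnt} in {cls}")
            if dist and max(dist) > self.n_years:
                raise ConfigError(
                    f"{cls}: max tenure {max(dist)} exceeds n_years "
                    f"{self.n_years}"
                )
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ConfigError(f"unknown condition {c!r}")
            if self.reps_per_condition.get(c, 0) < 2:
                raise ConfigError(f"{c}: every trial needs >= 2 replicates")
            if c == "MET":
                if len(self.met_locations_per_year) != self.n_years:
                    raise ConfigError(
                        "met_locations_per_year must have one count per year"
                    )
                if min(self.met_locations_per_year) < 1:
                    raise ConfigError("every MET year needs >= 1 location")
            elif not self.locations_per_condition.get(c):
                raise ConfigError(f"{c}: needs >= 1 location")
        if self.block_size < 2:
            raise ConfigError("block_size must be >= 2")
        self.truth.validate()


@dataclass
class ProgramTruth:
    """Realized truth of one generated program."""

    config: ProgramConfig
    truth: TruthRecord
    seed: int
    #: hybrid, hybrid_class, first_year, tenure, a (standardized shared
    #: deviation) and one genetic-deviation column g_<condition> each
    hybrids: pd.DataFrame
    #: condition, location, year, environment, residual_variance, low_h2
    environments: pd.DataFrame

    def genetic_value(self, condition: str) -> pd.Series:
        """Total genetic value per hybrid under one condition
        (class offset + trend * first-year index + deviation)."""
        t = self.truth
        h = self.hybrids
        trend = t.trend_per_condition.get(condition, 0.0)
        carries = h["hybrid_class"].isin(t.trend_classes)
        fy = h["first_year"] - self.config.start_year
        val = (
            h["hybrid_class"].map(t.class_offset).astype(float)
            + np.where(carries, trend * fy, 0.0)
            + h[f"g_{condition}"]
        )
        return pd.Series(val.to_numpy(), index=h["hybrid"], name=condition)


def _assign_entries(config: ProgramConfig) -> pd.DataFrame:
    """Hybrid ids, classes, tenures and packed first years.

    Entries are packed deterministically: within each class and tenure,
    first years cycle over the feasible range so every program year
    receives new entries and multi-year entries tie the years together.
    """
    rows = []
    counter = 0
    for cls in HYBRID_CLASSES:
        dist = config.tenure_distribution.get(cls, {})
        for tenure in sorted(dist, reverse=True):
            feasible = config.n_years - tenure + 1
            for i in range(dist[tenure]):
                counter += 1
                first = config.start_year + (i % feasible)
                rows.append((f"H{counter:03d}", cls, first, tenure))
    df = pd.DataFrame(rows, columns=["hybrid", "hybrid_class",
                                     "first_year", "tenure"])
    if df.empty:
        raise ConfigError("no entries configured")
    return df


def _environment_table(config: ProgramConfig, rng) -> pd.DataFrame:
    """One row per condition-location-year environment with its residual
    variance and low-h2 flag."""
    t = config.truth
    rows = []
    for cond in config.conditions:
        for iy in range(config.n_years):
            year = config.start_year + iy
            if cond == "MET":
                locs = [f"SITE{iy + 1:02d}_{j + 1:02d}"
                        for j in range(config.met_locations_per_year[iy])]
            else:
                locs = list(config.locations_per_condition[cond])
            for loc in locs:
                rows.append((cond, loc, year))
    env = pd.DataFrame(rows, columns=["condition", "location", "year"])
    env["environment"] = (
        env["condition"] + "|" + env["location"] + "|" + env["year"].astype(str)
    )
    base = env["condition"].map(t.residual_variance_per_condition)
    jitter = np.exp(rng.normal(0.0, t.residual_lognorm_sd, len(env)))
    env["residual_variance"] = base * jitter
    env["low_h2"] = False
    for cond, frac in t.low_h2_fraction.items():
        idx = env.index[env["condition"] == cond]
        n_low = int(round(frac * len(idx)))
        if n_low:
            chosen = rng.choice(idx, size=n_low, replace=False)
            env.loc[chosen, "low_h2"] = True
    return env


def build_program(
    config: ProgramConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, ProgramTruth]:
    """Generate the full plot-level trial table plus its truth record.

    One row per condition x year x location x replicate x hybrid plot;
    every entry appears once per replicate of every trial in its tenure
    window, in incomplete blocks of ``config.block_size`` plots.  The same
    seed and config give a byte-identical table.
    """
    config = config or ProgramConfig()
    config.validate()
    t = config.truth
    seed = t.rng_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    # field layout (entry order within replicates, hence blocks) comes from
    # a fixed stream so different noise seeds share the design skeleton
    design_rng = np.random.default_rng(961748927)

    hybrids = _assign_entries(config)
    nh = len(hybrids)

    # equicorrelated genetic deviations across conditions via a shared factor
    rho = t.condition_genetic_corr
    sg = np.sqrt(t.sigma2_G)
    z_shared = rng.normal(size=nh)
    a = {}
    for cond in CONDITIONS:  # draw for all conditions for a stable stream
        z_own = rng.normal(size=nh)
        a[cond] = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_own
    for cond in CONDITIONS:
        hybrids[f"g_{cond}"] = sg * a[cond]
    hybrids["a_shared"] = z_shared

    # hybrid-level genetic values of secondary traits (anchored to the
    # standardized per-condition yield deviation)
    trait_gen: dict[tuple[str, str], np.ndarray] = {}
    for tm in t.trait_models:
        eta = rng.normal(size=nh)
        for cond in tm.conditions:
            if cond not in CONDITIONS:
                raise ConfigError(f"trait {tm.name}: unknown condition {cond}")
            anchor = a[cond]
            if tm.kind == "count":
                trait_gen[(tm.name, cond)] = (
                    tm.r_g * anchor
                    + np.sqrt(max(0.0, 1 - tm.r_g**2)) * eta * 0.3
                )
            else:
                trait_gen[(tm.name, cond)] = tm.mean + tm.genetic_sd * (
                    tm.r_g * anchor + np.sqrt(max(0.0, 1 - tm.r_g**2)) * eta
                )

    env = _environment_table(config, rng)

    years = np.arange(config.start_year, config.start_year + config.n_years)
    year_eff = {
        (cond, y): rng.normal(0, np.sqrt(t.sigma2_Y))
        for cond in config.conditions for y in years
    }
    loc_eff = {
        row.environment: rng.normal(0, np.sqrt(t.sigma2_S))
        for row in env.itertuples()
    }
    gy_eff = {
        cond: rng.normal(0, np.sqrt(t.sigma2_GY), (nh, config.n_years))
        for cond in config.conditions
    }

    hyb_idx = {h: i for i, h in enumerate(hybrids["hybrid"])}
    first = hybrids["first_year"].to_numpy()
    last = first + hybrids["tenure"].to_numpy() - 1
    carries = hybrids["hybrid_class"].isin(t.trend_classes).to_numpy()
    cls_off = hybrids["hybrid_class"].map(t.class_offset).to_numpy(float)

    trait_cols = [tm.name for tm in t.trait_models]
    records: list[dict] = []
    for erow in env.itertuples():
        cond, loc, year = erow.condition, erow.location, erow.year
        active = np.where((first <= year) & (year <= last))[0]
        if len(active) == 0:
            continue
        iy = year - config.start_year
        scale_env = t.low_h2_scale if erow.low_h2 else 1.0
        trend = t.trend_per_condition.get(cond, 0.0)
        sig_e = np.sqrt(erow.residual_variance)
        n_reps = config.reps_per_condition[cond]
        gvals = (
            cls_off[active]
            + np.where(carries[active],
                       trend * (first[active] - config.start_year), 0.0)
            + hybrids[f"g_{cond}"].to_numpy()[active]
        )
        gy = gy_eff[cond][active, iy]
        base = (
            t.condition_mean.get(cond, 0.0)
            + year_eff[(cond, year)]
            + loc_eff[erow.environment]
        )
        n_act = len(active)
        tvals = {}
        for tm in t.trait_models:
            key = (tm.name, cond)
            tvals[tm.name] = trait_gen.get(key)
        for rep in range(1, n_reps + 1):
            rep_e = rng.normal(0, np.sqrt(t.sigma2_R))
            order = design_rng.permutation(n_act)
            n_blocks = int(np.ceil(n_act / config.block_size))
            block_e = rng.normal(0, np.sqrt(t.sigma2_B), n_blocks)
            noise = rng.normal(0, sig_e, n_act)
            # per-plot secondary-trait noise, one stream per trait
            tnoise = {
                tm.name: rng.normal(0, tm.noise_sd, n_act)
                for tm in t.trait_models
            }
            for pos, j in enumerate(order):
                hidx = active[j]
                b = pos // config.block_size + 1
                yld = (
                    base
                    + scale_env * (gvals[j] + gy[j])
                    + rep_e
                    + block_e[b - 1]
                    + noise[pos]
                )
                rec = {
                    "condition": cond,
                    "year": year,
                    "location": loc,
                    "replicate": rep,
                    "block": b,
                    "hybrid": hybrids["hybrid"].iat[hidx],
                    "hybrid_class": hybrids["hybrid_class"].iat[hidx],
                    "grain_yield": max(yld, 0.0)
                    if t.clip_negative_yields else yld,
                }
                anth = silk = None
                for tm in t.trait_models:
                    gv = tvals[tm.name]
                    if gv is None:
                        rec[tm.name] = np.nan
                        continue
                    raw = gv[hidx]
                    if erow.low_h2:
                        raw = tm.mean + scale_env * (raw - tm.mean) \
                            if tm.kind != "count" else scale_env * raw
                    if tm.kind == "count":
                        lam = np.exp(np.log(tm.mean) + raw
                                     + tnoise[tm.name][pos])
                        rec[tm.name] = int(rng.poisson(lam))
                    else:
                        val = raw + tnoise[tm.name][pos]
                        if tm.kind == "score":
                            rec[tm.name] = float(np.clip(round(val), 1, 9))
                        elif tm.kind == "days":
                            rec[tm.name] = float(round(val))
                        else:
                            rec[tm.name] = float(max(val, 0.0)) \
                                if tm.name == "ears_per_plant" else float(val)
                    if tm.name == "days_anthesis":
                        anth = rec[tm.name]
                    if tm.name == "asi":
                        silk = None if anth is None else anth + rec[tm.name]
                if anth is not None and silk is not None:
                    rec["days_silking"] = silk
                    rec["asi"] = silk - anth
                records.append(rec)

    plots = pd.DataFrame.from_records(records)
    front = ["condition", "year", "location", "replicate", "block",
             "hybrid", "hybrid_class", "grain_yield"]
    tail = [c for c in ("days_anthesis", "days_silking", "asi",
                        "plant_height", "ear_height", "ears_per_plant",
                        "ear_aspect", "striga_damage_8wk",
                        "striga_damage_10wk", "striga_count_8wk",
                        "striga_count_10wk") if c in plots.columns]
    plots = plots[front + tail]

    truth_out = ProgramTruth(
        config=config, truth=t, seed=seed,
        hybrids=hybrids, environments=env,
    )
    return plots, truth_out


def tenure_summary(plots: pd.DataFrame) -> dict[str, dict[int, int]]:
    """Distinct hybrids per class by number of distinct years tested."""
    if plots.empty:
        raise ValueError("empty plot table")
    per_hyb = (
        plots.groupby("hybrid")
        .agg(hybrid_class=("hybrid_class", "first"),
             n_years=("year", "nunique"))
    )
    out: dict[str, dict[int, int]] = {}
    for cls, sub in per_hyb.groupby("hybrid_class", observed=True):
        out[str(cls)] = {
            int(k): int(v) for k, v in
            sub["n_years"].value_counts().sort_index().items()
        }
    return out


def simulate_adjusted_means(
    n_hybrids: int,
    conditions=("MDS", "STRIN"),
    *,
    r_g: float = 0.5,
    sigma2_G: float = 200_000.0,
    mu: float = 3000.0,
    se_range: tuple[float, float] = (60.0, 120.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Hybrid adjusted means under several conditions with known genetic
    correlation — the input level of the between-condition correlation
    estimator (stage-1 estimation error enters as mean-level noise with
    known standard errors).

    Default SEs (60-120 kg/ha) reflect adjusted means estimated from a
    large multi-environment series.  The variance-ratio correlation treats
    all cross-condition covariance as genetic and everything else as
    residual, so heavy mean-level noise attenuates it toward the plain
    Pearson correlation of the means."""
    if not 0 <= r_g <= 1:
        raise ConfigError("r_g must be in [0, 1] for equicorrelated draws")
    rng = np.random.default_rng(seed)
    sg = np.sqrt(sigma2_G)
    shared = rng.normal(size=n_hybrids)
    rows = []
    for cond in conditions:
        own = rng.normal(size=n_hybrids)
        g = sg * (np.sqrt(r_g) * shared + np.sqrt(1 - r_g) * own)
        se = rng.uniform(*se_range, n_hybrids)
        est = mu + g + rng.normal(0, se)
        for i in range(n_hybrids):
            rows.append((f"H{i + 1:03d}", cond, est[i], se[i]))
    return pd.DataFrame(rows, columns=["hybrid", "condition",
                                       "estimate", "se"])


def truth_to_dict(pt: ProgramTruth) -> dict:
    """YAML-serializable realized-truth structure."""
    return {
        "seed": pt.seed,
        "truth": dataclasses.asdict(pt.truth) | {
            "trait_models": [dataclasses.asdict(tm)
                             for tm in pt.truth.trait_models],
        },
        "hybrids": pt.hybrids.to_dict(orient="list"),
        "environments": pt.environments.to_dict(orient="list"),
    }
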