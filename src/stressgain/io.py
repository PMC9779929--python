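"""Long-format trial-table I/O, validation and derived traits.

The canonical table has one row per plot: the growing condition, calendar
year, location, replicate, incomplete block, hybrid id and class, followed
by trait columns (grain yield at 15% moisture in kg/ha, flowering dates,
ASI, heights, ears per plant, ear aspect, and the Striga damage ratings and
emerged-parasite counts recorded under infestation).  CSV dialect:
comma-separated, UTF-8, '.' decimal, one header row.  Missing values are
allowed in trait columns only and are never imputed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml

from .simulate import CONDITIONS, HYBRID_CLASSES, ProgramConfig, TruthRecord, TraitModel

__all__ = [
    "FACTOR_COLUMNS",
    "TRAIT_COLUMNS",
    "PLOT_KEY",
    "TrialFormatError",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "with_environment",
    "environment_key",
    "yield_from_ears",
    "asi",
    "save_config",
    "load_config",
]

FACTOR_COLUMNS = (
    "condition", "year", "location", "replicate", "block",
    "hybrid", "hybrid_class",
)
TRAIT_COLUMNS = (
    "grain_yield", "days_anthesis", "days_silking", "asi",
    "plant_height", "ear_height", "ears_per_plant", "ear_aspect",
    "striga_damage_8wk", "striga_damage_10wk",
    "striga_count_8wk", "striga_count_10wk",
)
#: a plot is identified by this key (block is determined by it)
PLOT_KEY = ("condition", "year", "location", "replicate", "hybrid")

_SCORE_COLUMNS = ("ear_aspect", "striga_damage_8wk", "striga_damage_10wk")
_COUNT_COLUMNS = ("striga_count_8wk", "striga_count_10wk")
_POSITIVE_COLUMNS = ("days_anthesis", "days_silking",
                     "plant_height", "ear_height")


class TrialFormatError(ValueError):
    """The file does not have the required layout."""


class TrialValidationError(ValueError):
    """Rows violate table invariants; carries row-level diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "\n".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n... {len(problems)-20} more"
        super().__init__(f"{len(problems)} invalid rows:\n{preview}{more}")


def validate_trials(df: pd.DataFrame) -> list[str]:
    """Return row-level diagnostics (empty when the table is valid)."""
    problems: list[str] = []

    def bad(mask, field, msg):
        for i in df.index[np.asarray(mask)]:
            problems.append(f"row {i}: {field}: {msg}")

    bad(~df["condition"].isin(CONDITIONS), "condition",
        f"must be one of {CONDITIONS}")
    bad(~df["hybrid_class"].isin(HYBRID_CLASSES), "hybrid_class",
        f"must be one of {HYBRID_CLASSES}")
    bad(df["replicate"] < 1, "replicate", "must be >= 1")
    bad(df["block"] < 1, "block", "must be >= 1")
    for col in _SCORE_COLUMNS:
        if col in df:
            v = df[col]
            bad(v.notna() & ((v < 1) | (v > 9)), col, "score outside [1, 9]")
    for col in _COUNT_COLUMNS:
        if col in df:
            v = df[col]
            bad(v.notna() & (v < 0), col, "count must be >= 0")
            bad(v.notna() & (v % 1 != 0), col, "count must be an integer")
    for col in _POSITIVE_COLUMNS:
        if col in df:
            v = df[col]
            bad(v.notna() & (v <= 0), col, "must be > 0")
    if "grain_yield" in df:
        v = df["grain_yield"]
        bad(v.notna() & (v < 0), "grain_yield", "must be >= 0")
    if "ears_per_plant" in df:
        v = df["ears_per_plant"]
        bad(v.notna() & (v < 0), "ears_per_plant", "must be >= 0")
    if {"days_anthesis", "days_silking", "asi"} <= set(df.columns):
        both = df["days_anthesis"].notna() & df["days_silking"].notna()
        expect = df["days_silking"] - df["days_anthesis"]
        bad(both & df["asi"].notna()
            & (np.abs(df["asi"] - expect) > 1e-6),
            "asi", "asi != days_silking - days_anthesis")

    dup = df.duplicated(subset=list(PLOT_KEY), keep=False)
    if dup.any():
        for i in df.index[dup]:
            key = tuple(df.loc[i, list(PLOT_KEY)])
            problems.append(f"row {i}: duplicate plot key {key}")
    return problems


def read_trials(path, *, validate: bool = True) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    Raises :class:`TrialFormatError` when a required factor column is
    missing and :class:`TrialValidationError` (with row-level diagnostics)
    when rows violate the table invariants.
    """
    df = pd.read_csv(path)
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing required factor columns: {missing}")
    if df[list(FACTOR_COLUMNS)].isna().any().any():
        raise TrialFormatError("missing values in factor columns")
    df["year"] = df["year"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["block"] = df["block"].astype(int)
    for col in ("condition", "location", "hybrid", "hybrid_class"):
        df[col] = df[col].astype(str)
    for col in TRAIT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if validate:
        problems = validate_trials(df)
        if problems:
            raise TrialValidationError(problems)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the trial table as CSV (UTF-8, '.' decimal, one header row)."""
    df.to_csv(path, index=False)


def environment_key(df: pd.DataFrame) -> pd.Series:
    """'condition|location|year' identifier of each row's environment."""
    return (df["condition"].astype(str) + "|" + df["location"].astype(str)
            + "|" + df["year"].astype(str))


def with_environment(df: pd.DataFrame) -> pd.DataFrame:
    """Copy of the table with an 'environment' column appended."""
    out = df.copy()
    out["environment"] = environment_key(df)
    return out


def yield_from_ears(ear_weight, moisture, plot_area, *,
                    shelling: float = 0.80, target_moisture: float = 15.0):
    """Grain yield (kg/ha at the target moisture) from plot ear weight.

    Applies the shelling percentage and the dry-matter-preserving moisture
    adjustment (100 - m) / (100 - target), then scales plot kg to kg/ha:

        ear_weight * shelling * (100 - moisture)/(100 - target) / area * 1e4
    """
    ear_weight = np.asarray(ear_weight, dtype=float)
    moisture = np.asarray(moisture, dtype=float)
    plot_area = np.asarray(plot_area, dtype=float)
    if np.any(moisture >= 100) or np.any(moisture < 0):
        raise ValueError("moisture must be in [0, 100)")
    if np.any(plot_area <= 0):
        raise ValueError("plot_area must be > 0")
    if np.any(ear_weight < 0):
        raise ValueError("ear_weight must be >= 0")
    out = (ear_weight * shelling * (100.0 - moisture)
           / (100.0 - target_moisture) / plot_area * 10_000.0)
    return float(out) if out.ndim == 0 else out


def asi(days_anthesis, days_silking):
    """Anthesis-silking interval (days): silking minus anthesis.

    Negative values indicate silking before anthesis; a missing parent
    yields a missing result, not an error.
    """
    a = np.asarray(days_anthesis, dtype=float)
    s = np.asarray(days_silking, dtype=float)
    out = s - a
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------- config IO

def save_config(config: ProgramConfig, path, extra: dict | None = None):
    """Write a ProgramConfig (plus optional qc/trend/model sections) as YAML."""
    tr = dataclasses.asdict(config.truth)
    tr["trait_models"] = [dataclasses.asdict(tm)
                          for tm in config.truth.trait_models]
    prog = dataclasses.asdict(config)
    prog["truth"] = tr
    doc = {"program": prog}
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(doc), fh, sort_keys=False)


def load_config(path) -> tuple[ProgramConfig, dict]:
    """Read a YAML pipeline config; returns (ProgramConfig, other sections)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    prog = doc.pop("program", {})
    truth_d = prog.pop("truth", {})
    tms = truth_d.pop("trait_models", None)
    if tms is not None:
        truth_d["trait_models"] = tuple(TraitModel(**tm) for tm in tms)
    for key in ("trend_classes",):
        if key in truth_d:
            truth_d[key] = tuple(truth_d[key])
    truth = TruthRecord(**truth_d)
    for key in ("conditions", "met_locations_per_year"):
        if key in prog:
            prog[key] = tuple(prog[key])
    if "locations_per_condition" in prog:
        prog["locations_per_condition"] = {
            k: tuple(v) for k, v in prog["locations_per_condition"].items()
        }
    if "tenure_distribution" in prog:
        prog["tenure_distribution"] = {
            cls: {int(t): int(c) for t, c in d.items()}
            for cls, d in prog["tenure_distribution"].items()
        }
    config = ProgramConfig(truth=truth, **prog)
    config.validate()
    return config, doc


def _plain(obj):
    """Recursively convert numpy/tuple values to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
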