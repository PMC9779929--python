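"""Genetic correlations between growing conditions and with key traits.

Between conditions: the hybrid adjusted means from stage 1 are modelled
with a common genetic effect, fixed condition effects and per-condition
residual variances; the correlation for each pair is the variance ratio
sigma2_G / sqrt((sigma2_G + s2_p)(sigma2_G + s2_p')).  Between traits:
bivariate mixed models with an unstructured genetic covariance, fitted to
per-hybrid means of yield and each stress-relevant trait under managed
drought (MDS) and Striga infestation (STRIN).

Writes ``env_correlations.csv`` (matrix), ``env_correlation_pairs.csv``
(r +- SE per pair) and ``trait_correlations.csv``.
"""

import argparse
import sys
import warnings
from pathlib import Path

import pandas as pd

from stressgain.gencorr import (
    bivariate_trait_correlation,
    env_genetic_correlations,
)
from stressgain.io import read_trials

ROOT = Path(__file__).resolve().parents[1]

TRAITS_BY_CONDITION = {
    "MDS": ["days_anthesis", "asi", "plant_height", "ear_height",
            "ears_per_plant"],
    "STRIN": ["days_anthesis", "plant_height", "ears_per_plant",
              "ear_aspect", "striga_damage_8wk", "striga_count_8wk"],
}


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args(argv)

    means = pd.read_csv(args.results / "adjusted_means.csv")
    mat, pairs = env_genetic_correlations(means)
    mat.to_csv(args.results / "env_correlations.csv")
    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(
        args.results / "env_correlation_pairs.csv", index=False
    )
    print("between-condition genetic correlations (r +- SE):")
    for p in pairs:
        print(f"  {p.a:6s} x {p.b:6s}: {p.r:5.2f} +- {p.se:.2f}")

    plots = read_trials(args.results / "trial_data.csv")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cond, traits in TRAITS_BY_CONDITION.items():
            for tr in traits:
                est = bivariate_trait_correlation(
                    plots, "grain_yield", tr, cond, level="plots"
                )
                rows.append(dict(condition=cond, trait=tr, r=est.r,
                                 se=est.se, boundary=est.boundary))
                print(f"  {cond:6s} yield x {tr:18s}: "
                      f"{est.r:5.2f} +- {est.se:.2f}")
    pd.DataFrame(rows).to_csv(
        args.results / "trait_correlations.csv", index=False
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
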