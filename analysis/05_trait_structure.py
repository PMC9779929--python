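"""Trait structure: PCA on hybrid trait BLUPs and yield-on-PC1 regression.

For MDS and STRIN separately: per-hybrid BLUPs of yield and the
stress-relevant traits, PCA of their correlation matrix, Pearson
correlations of each trait with each axis, and an OLS regression of the
yield BLUPs on the PC1 scores.  Writes loadings, proportions, trait-axis
correlations and the regression summary per condition, plus a PC1-yield
scatter plot.
"""

import argparse
import sys
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from stressgain.io import read_trials
from stressgain.traits import (
    hybrid_blups,
    pca_blups,
    trait_pc_correlations,
    yield_on_pc1,
)

ROOT = Path(__file__).resolve().parents[1]

TRAITS_BY_CONDITION = {
    "MDS": ["grain_yield", "days_anthesis", "asi", "plant_height",
            "ear_height", "ears_per_plant"],
    "STRIN": ["grain_yield", "days_anthesis", "plant_height",
              "ears_per_plant", "ear_aspect", "striga_damage_8wk",
              "striga_count_8wk"],
}


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args(argv)

    plots = read_trials(args.results / "trial_data.csv")
    for cond, traits in TRAITS_BY_CONDITION.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = hybrid_blups(plots, traits, cond)
            res = pca_blups(m)
        corr = trait_pc_correlations(m, res.scores)
        reg = yield_on_pc1(m.loc[res.scores.index, "grain_yield"],
                           res.scores["PC1"])

        res.loadings.to_csv(args.results / f"pca_loadings_{cond}.csv")
        corr.to_csv(args.results / f"pca_trait_correlations_{cond}.csv")
        pd.Series(res.proportions,
                  index=res.loadings.columns).to_csv(
            args.results / f"pca_proportions_{cond}.csv", header=False
        )
        pd.DataFrame([reg.__dict__]).to_csv(
            args.results / f"yield_on_pc1_{cond}.csv", index=False
        )

        print(f"{cond}: PC1 explains {100 * res.proportions[0]:.0f}% of "
              f"trait variation; yield~PC1 slope {reg.slope:.1f} "
              f"(R2={reg.r2:.2f}, p={reg.p:.2g})")
        lead = corr["PC1"].abs().sort_values(ascending=False).head(3)
        print(f"  traits driving PC1: {', '.join(lead.index)}")

        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(res.scores["PC1"],
                   m.loc[res.scores.index, "grain_yield"], s=12, alpha=0.7)
        ax.set_xlabel("PC1 score")
        ax.set_ylabel("yield BLUP (kg/ha)")
        ax.set_title(f"{cond}: yield vs PC1 (R2={reg.r2:.2f})")
        fig.tight_layout()
        fig.savefig(args.results / f"yield_pc1_{cond}.png", dpi=120)
        plt.close(fig)
    return 0


if __name__ == "__main__":
    sys.exit(main())
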