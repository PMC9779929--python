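"""Per-trial repeatability and the 0.2 filter.

Reads results/trial_data.csv, fits every location-year environment with
hybrids random, computes generalized (Cullis) repeatability, and writes

* ``qc.csv`` — one row per environment (h2, variance components, kept flag)
* ``kept_environments.txt`` — the environments retained for trend analysis

and prints the per-condition repeatability ranges with discard counts.
"""

import argparse
import sys
from pathlib import Path

from stressgain.io import read_trials
from stressgain.qc import filter_trials, qc_environments

ROOT = Path(__file__).resolve().parents[1]


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--threshold", type=float, default=0.2)
    args = ap.parse_args(argv)

    plots = read_trials(args.results / "trial_data.csv")
    qc = qc_environments(plots)
    kept, discarded = filter_trials(qc, args.threshold)
    qc_out = qc.copy()
    qc_out["kept"] = qc_out["h2"] >= args.threshold
    qc_out.to_csv(args.results / "qc.csv", index=False)
    (args.results / "kept_environments.txt").write_text(
        "\n".join(kept["environment"]) + "\n"
    )

    for cond, sub in qc_out.groupby("condition"):
        n_disc = int((~sub.kept).sum())
        print(f"{cond:6s}: repeatability {sub.h2.min():.2f}-{sub.h2.max():.2f}"
              f" over {len(sub)} trials; {n_disc} discarded (h2 < "
              f"{args.threshold})")
    print(f"kept {len(kept)} of {len(qc)} environments "
          f"-> {args.results / 'kept_environments.txt'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
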