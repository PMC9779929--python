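"""Check-relative performance and stress-reduction descriptives.

From the stage-1 adjusted means: the best 44 DTSTR hybrids tested at
least two years versus the commercial (STRCOM, CONCOM) and local checks
under each condition, and the yearly percent yield reduction of managed
drought relative to the well-watered control.  Writes
``check_comparisons.csv`` and ``stress_reduction.csv``.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from stressgain.io import read_trials
from stressgain.summaries import (
    ComparisonError,
    group_relative_yield,
    stress_reduction,
)

ROOT = Path(__file__).resolve().parents[1]


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--top-k", type=int, default=44)
    ap.add_argument("--min-years", type=int, default=2)
    args = ap.parse_args(argv)

    means = pd.read_csv(args.results / "adjusted_means.csv")
    rows = []
    for cond in sorted(means.condition.unique()):
        for checks in (("STRCOM",), ("CONCOM",), ("LOCAL",)):
            try:
                cmp = group_relative_yield(
                    means, ("DTSTR",), checks,
                    min_years=args.min_years if checks != ("LOCAL",) else 0,
                    top_k_a=args.top_k, condition=cond,
                )
            except ComparisonError:
                continue
            rows.append(cmp.__dict__)
            print(f"{cond:6s}: best {cmp.n_a} DTSTR vs {cmp.label_b:7s}"
                  f" ({cmp.n_b}): {cmp.relative_gain:+.0f}%")
    pd.DataFrame(rows).to_csv(args.results / "check_comparisons.csv",
                              index=False)

    plots = read_trials(args.results / "trial_data.csv")
    sr_rows = []
    for year in sorted(plots.year.unique()):
        mds = plots.query("condition == 'MDS' and year == @year")
        ww = plots.query("condition == 'WW' and year == @year")
        if mds.empty or ww.empty:
            continue
        red = stress_reduction(mds.grain_yield.mean(), ww.grain_yield.mean())
        sr_rows.append(dict(year=year, reduction_pct=red,
                            mds_mean=mds.grain_yield.mean(),
                            ww_mean=ww.grain_yield.mean()))
    sr = pd.DataFrame(sr_rows)
    sr.to_csv(args.results / "stress_reduction.csv", index=False)
    print("drought stress reduced mean yields by "
          + ", ".join(f"{r.reduction_pct:.0f}% in {int(r.year)}"
                      for r in sr.itertuples()))
    return 0


if __name__ == "__main__":
    sys.exit(main())
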