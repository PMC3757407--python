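#!/usr/bin/env python
"""Benefit of shortening the screening interval, per half-year step.

For each trial and each change 1->0.5, 1.5->1 and 2->1.5 years, computes
the percent increase in the mean lead time and in Q (the proportion of
clinical cases whose diagnosis screening advances), from the exact
analytic summaries.
"""

import argparse
from pathlib import Path

from leadtime import build_summary_table, percent_increases, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    grid = build_summary_table(engine="analytic")
    benefit = percent_increases(grid)
    out = write_table(benefit, args.outdir / "interval_benefit.csv")

    print(benefit.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    hip = benefit[(benefit.trial == "HIP") & (benefit.from_delta == 1.0)].iloc[0]
    print(f"\nWrote {out}")
    print(
        "Every half-year cut raises both quantities for every trial.  For a "
        "woman screened yearly under the HIP parameters, moving to "
        f"half-yearly exams raises her chance of an early detection by "
        f"{hip.pct_increase_q:.2f}% and the expected lead time by "
        f"{hip.pct_increase_mean:.2f}%."
    )


if __name__ == "__main__":
    main()
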