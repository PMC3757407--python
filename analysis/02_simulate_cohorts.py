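#!/usr/bin/env python
"""Monte-Carlo replication of the lead-time summary table.

Simulates one million accepted clinical cases per (trial, interval) cell
under the stable natural-history model and compares the empirical
summaries against the deterministic closed-form/analytic-moment engine.
The two routes share no code beyond the parameter containers, so their
agreement is a genuine end-to-end check of both.
"""

import argparse
from pathlib import Path

from leadtime import build_summary_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n", type=int, default=1_000_000,
                    help="accepted clinical cases per cell")
    ap.add_argument("--seed", type=int, default=20110426)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sim = build_summary_table(engine="simulation", n_cases=args.n, seed=args.seed)
    ana = build_summary_table(engine="analytic")

    out = write_table(sim, args.outdir / "lead_time_summary_simulated.csv")
    agree = sim[["trial", "delta", "n"]].copy()
    for col in ("P", "mean", "sd"):
        agree[f"{col}_sim"] = sim[col]
        agree[f"{col}_exact"] = ana[col]
    agree["P_gap_in_se"] = (sim["P"] - ana["P"]) / sim["se_p"]
    agree["mean_gap_in_se"] = (sim["mean"] - ana["mean"]) / sim["se_mean"]
    agree["sd_gap_in_se"] = (sim["sd"] - ana["sd"]) / sim["se_sd"]
    out2 = write_table(agree, args.outdir / "engine_agreement.csv")

    print(sim.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    worst = agree[["P_gap_in_se", "mean_gap_in_se", "sd_gap_in_se"]].abs().max().max()
    print(f"\nWrote {out} and {out2}")
    print(
        f"Largest simulated-vs-exact gap over all 16 cells and three "
        f"statistics: {worst:.2f} Monte-Carlo standard errors "
        f"(n = {args.n:,} accepted cases per cell)."
    )


if __name__ == "__main__":
    main()
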