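#!/usr/bin/env python
"""Assemble unadjusted index-year costs and the category summary table.

Strips the protocol-driven pressure wire from the angiography-only arm,
multiplies resource use by unit costs, and reports per-arm category means
with bootstrap percentile CIs plus FFR - standard differences (the raw
unadjusted cost table of the analysis). Writes results/table_costs.csv.
"""

from pathlib import Path

import pandas as pd

from ffrcea.config import load_unit_costs
from ffrcea.costing import assemble_costs, strip_protocol_costs, summarise_costs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "patients.csv")
    unit_costs = load_unit_costs()
    costs = assemble_costs(strip_protocol_costs(table), unit_costs)
    summary = summarise_costs(costs, n_boot=2000, seed=20140102)
    summary.to_csv(OUT / "table_costs.csv")

    show = summary[["mean_standard", "mean_ffr", "difference"]].round(0).astype(int)
    print("unadjusted mean per-patient costs (GBP):")
    print(show)
    diff = summary.loc["total", "difference"]
    lo, hi = summary.loc["total", ["ci_low_difference", "ci_high_difference"]]
    print(f"\ntotal incremental cost (FFR - standard): "
          f"£{diff:.0f} (95% CI {lo:.0f} to {hi:.0f})")
    print(f"wrote {OUT / 'table_costs.csv'}")


if __name__ == "__main__":
    main()
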