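#!/usr/bin/env python
"""Average operating-range behavior by compliance class and limb.

Bins the sweep into low (T/M < 2) vs high compliance and
ascending/plateau/descending passive-length classes and reports, per
activation level and model variant, the mean normalized fiber length,
mean normalized force, and mean length change from the passive state —
the coarse picture of how activation drags compliant muscles down the
force-length curve.
"""

from pathlib import Path

import pandas as pd

from mtusim import group_summaries

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

table = pd.read_csv(OUT / "sweep_table1.csv")
summaries = group_summaries(table)
summaries.to_csv(OUT / "group_summaries.csv", index=False)

print(f"{len(summaries)} group cells written")
full = summaries[
    (summaries["activation"] == 1.0) & (summaries["variant"] == "CNS")
]
print("\nmean fiber-length change from passive at 100% activation (CNS):")
for _, row in full.iterrows():
    print(f"  {row['compliance_class']:>4} compliance, limb {row['limb']}: "
          f"dL = {row['mean_delta_length']:+.3f} L0  "
          f"(mean force {row['mean_norm_force']:.2f} F100max, n={int(row['n'])})")
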