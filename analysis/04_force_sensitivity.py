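#!/usr/bin/env python
"""Where do compliance and the activation-dependent shift matter?

Compares model variants condition by condition through the relative force
change %dF and bins the results on a (passive length x T/M ratio) grid,
reporting per bin the fraction of conditions with |%dF| > 10%.  Three maps
are produced: compliance at full and at 25% activation (rigid vs compliant
tendon) and the activation-dependent shift at 25% activation (compliant
without vs with shift).  Prints each compliance band's zero-fraction
"trough" — the passive lengths where the simpler model is safe to use.
"""

from pathlib import Path

import pandas as pd

from mtusim import sensitivity_map

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

table = pd.read_csv(OUT / "sweep_table1.csv")

maps = [
    (("NCNS", "CNS"), 1.0),
    (("NCNS", "CNS"), 0.25),
    (("CNS", "CS"), 0.25),
]
for pair, activation in maps:
    bins = sensitivity_map(table, pair, activation=activation)
    stem = f"sensitivity_{pair[0]}_{pair[1]}_a{int(activation * 100)}"
    bins.to_csv(OUT / f"{stem}.csv", index=False)
    n_hot = int((bins["frac_exceeding"] == 1.0).sum())
    print(f"\n{pair[0]} vs {pair[1]} at {activation:.0%} activation: "
          f"{len(bins)} bins, {n_hot} fully above the 10% criterion")
    for tm_lo, sub in bins.groupby("tm_lo"):
        sub = sub.sort_values("length_bin")
        zeros = sub[sub["frac_exceeding"] == 0]
        if zeros.empty:
            print(f"  T/M [{tm_lo:5.1f},{sub['tm_hi'].iloc[0]:5.1f}): "
                  "no trough - the simpler model errs >10% at every length")
        else:
            print(f"  T/M [{tm_lo:5.1f},{sub['tm_hi'].iloc[0]:5.1f}): "
                  f"trough at passive lengths "
                  f"[{zeros['length_lo'].min():.2f}, {zeros['length_hi'].max():.2f})")
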