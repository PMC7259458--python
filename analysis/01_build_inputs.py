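#!/usr/bin/env python
"""Assemble the study inputs.

Writes the packaged 39-muscle parameter table (21 hip + 18 ankle actuators
with their tendon slack lengths and optimal fiber lengths), and two
synthetic single-joint geometries that mirror the limb's proximal-distal
compliance gradient: a low-compliance "hip-like" joint whose muscles rest
on the ascending limb of the force-length curve, and a high-compliance
"ankle-like" joint resting on the descending limb.
"""

from pathlib import Path

import numpy as np

from mtusim import (
    CurveSet,
    JointSpec,
    SynthesisSpec,
    generate_joint_geometry,
    generate_muscles,
    table1_fixture,
)
from mtusim.io import write_geometry_json, write_muscles_csv

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

curves = CurveSet()

muscles = table1_fixture()
write_muscles_csv(muscles, OUT / "muscles_table1.csv")
hip = [m for m in muscles if m.group == "hip"]
ankle = [m for m in muscles if m.group == "ankle"]
print(f"muscle table: {len(muscles)} actuators "
      f"({len(hip)} hip, mean T/M {np.mean([m.tm_ratio for m in hip]):.2f}; "
      f"{len(ankle)} ankle, mean T/M {np.mean([m.tm_ratio for m in ankle]):.2f})")

for name, centers, limb, seed in (
    ("hip_like", (0.71, 0.71), "A", 3),
    ("ankle_like", (7.82, 7.82), "D", 4),
):
    spec = SynthesisSpec(
        n_muscles=10, tm_distribution="bimodal", bimodal_centers=centers,
        seed=seed, joint=JointSpec(limb=limb, reference_angle=0.0,
                                   angle_range=(-40.0, 40.0)),
    )
    geo = generate_joint_geometry(spec, generate_muscles(spec), curves, name)
    write_geometry_json(geo, OUT / f"joint_{name}.json")
    tm = np.mean([p.tm_ratio for p, _ in geo.muscles])
    print(f"joint {name}: 10 muscles, mean T/M {tm:.2f}, "
          f"passive limb target '{limb}' at the reference posture")
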