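"""File-format boundary: muscle CSVs, measurement CSVs, curve configs,
and joint-geometry JSON.

Muscle parameter CSV columns: ``name, tsl_m, l0_m, pennation_deg, fmax_n,
group`` (header required).  Curve parameters live under a ``curves:`` block
of a YAML (or JSON) config file; omitted keys keep their defaults.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd
import yaml

from .muscle_curves import CurveSet
from .mtu_equilibrium import MuscleParams
from .joint_capacity import JointGeometry

__all__ = [
    "read_muscles_csv",
    "write_muscles_csv",
    "load_curves",
    "read_geometry_json",
    "write_geometry_json",
]

MUSCLE_COLUMNS = ["name", "tsl_m", "l0_m", "pennation_deg", "fmax_n", "group"]


def read_muscles_csv(path) -> list[MuscleParams]:
    df = pd.read_csv(path)
    missing = set(MUSCLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"muscle CSV missing columns: {sorted(missing)}")
    return [
        MuscleParams(
            name=str(r.name),
            tendon_slack_length=float(r.tsl_m),
            optimal_fiber_length=float(r.l0_m),
            pennation_at_optimal=math.radians(float(r.pennation_deg)),
            f_max=float(r.fmax_n),
            group=str(r.group),
        )
        for r in df.itertuples(index=False)
    ]


def write_muscles_csv(muscles, path) -> None:
    pd.DataFrame(
        [
            {
                "name": m.name,
                "tsl_m": m.tendon_slack_length,
                "l0_m": m.optimal_fiber_length,
                "pennation_deg": math.degrees(m.pennation_at_optimal),
                "fmax_n": m.f_max,
                "group": m.group,
            }
            for m in muscles
        ]
    ).to_csv(path, index=False)


def load_curves(path=None) -> CurveSet:
    """CurveSet from the ``curves:`` block of a YAML/JSON config file."""
    if path is None:
        return CurveSet()
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    return CurveSet(**cfg.get("curves", {}))


def write_geometry_json(geometry: JointGeometry, path) -> None:
    """Serialize a joint with linear (constant-moment-arm) MTU lengths."""
    payload = {
        "joint_name": geometry.joint_name,
        "angle_range": list(geometry.angle_range),
        "reference_angle": geometry.reference_angle,
        "muscles": [
            {
                "name": m.name,
                "tsl_m": m.tendon_slack_length,
                "l0_m": m.optimal_fiber_length,
                "pennation_deg": math.degrees(m.pennation_at_optimal),
                "fmax_n": m.f_max,
                "group": m.group,
                "mtu_at_reference_m": fn(geometry.reference_angle),
                "moment_arm_m": getattr(fn, "moment_arm", None),
            }
            for m, fn in geometry.muscles
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_geometry_json(path) -> JointGeometry:
    data = json.loads(Path(path).read_text())
    ref = float(data["reference_angle"])
    pairs = []
    for entry in data["muscles"]:
        params = MuscleParams(
            name=entry["name"],
            tendon_slack_length=float(entry["tsl_m"]),
            optimal_fiber_length=float(entry["l0_m"]),
            pennation_at_optimal=math.radians(float(entry["pennation_deg"])),
            f_max=float(entry["fmax_n"]),
            group=entry.get("group", "synthetic"),
        )
        l_ref = float(entry["mtu_at_reference_m"])
        r = float(entry["moment_arm_m"])

        def length_fn(angle_deg, _l=l_ref, _r=r, _ref=ref):
            return _l - _r * math.radians(angle_deg - _ref)

        length_fn.moment_arm = r
        pairs.append((params, length_fn))
    return JointGeometry(
        joint_name=data["joint_name"],
        muscles=pairs,
        angle_range=tuple(data["angle_range"]),
        reference_angle=ref,
    )
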