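"""Input generators: the packaged reference muscle table, random muscle
sets with controlled tendon-to-fiber (T/M) ratio distributions, and
synthetic joint geometries.

The packaged table lists the 39 pelvic-limb actuators of a guinea fowl
model — 21 hip flexion/extension muscles (mean printed T/M ratio 0.71,
low compliance) and 18 ankle flexion/extension muscles (high compliance,
T/M up to 16.55) — with their tendon slack lengths and optimal fiber
lengths in meters.  Maximal isometric forces are not part of the printed
table; a uniform placeholder is used and flagged, which leaves every
normalized analysis unaffected.

Random generators emulate the same structure: T/M ratios either uniform
over a range or bimodal around a low-compliance "hip-like" and a
high-compliance "ankle-like" center, and per-muscle linear MTU-length
functions of joint angle with prescribed moment arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .muscle_curves import CurveSet
from .mtu_equilibrium import MuscleParams, mtu_length_for_passive_length
from .joint_capacity import JointGeometry

__all__ = [
    "SynthesisSpec",
    "JointSpec",
    "table1_fixture",
    "generate_muscles",
    "generate_joint_geometry",
    "TABLE1_ROWS",
]

#: (name, tendon slack length m, optimal fiber length m, printed T/M, group)
TABLE1_ROWS = [
    # hip flexion/extension muscles
    ("CFP", 0.027, 0.037, 0.71, "hip"),
    ("FCLP_c", 0.0, 0.120, 0.00, "hip"),
    ("FCLP_p", 0.078, 0.054, 1.46, "hip"),
    ("IC_cr", 0.0, 0.086, 0.00, "hip"),
    ("IC_cd", 0.0, 0.085, 0.00, "hip"),
    ("ILPO_cr", 0.064, 0.033, 1.93, "hip"),
    ("ILPO_m", 0.017, 0.083, 0.21, "hip"),
    ("ILPO_cd", 0.0, 0.111, 0.00, "hip"),
    ("ILPR_cr", 0.044, 0.041, 1.09, "hip"),
    ("ILPR_cd", 0.057, 0.026, 2.19, "hip"),
    ("ISF_v", 0.039, 0.014, 2.76, "hip"),
    ("ISF_d", 0.039, 0.014, 2.76, "hip"),
    ("ITC_d", 0.019, 0.023, 0.83, "hip"),
    ("ITC_v", 0.012, 0.028, 0.42, "hip"),
    ("ITCR", 0.006, 0.023, 0.28, "hip"),
    ("ITM", 0.008, 0.023, 0.33, "hip"),
    ("PIFL_cd", 0.0, 0.075, 0.00, "hip"),
    ("PIFL_cr", 0.0, 0.049, 0.00, "hip"),
    ("PIFM_cd", 0.0, 0.075, 0.00, "hip"),
    ("PIFM_cr", 0.0, 0.040, 0.00, "hip"),
    ("FCM", 0.003, 0.74, 0.01, "hip"),
    # ankle flexion/extension muscles
    ("DFii_d", 0.182, 0.011, 16.55, "ankle"),
    ("DFii_dx", 0.185, 0.015, 12.33, "ankle"),
    ("DFiii_dx", 0.196, 0.016, 12.33, "ankle"),
    ("DFiii_d", 0.195, 0.013, 14.77, "ankle"),
    ("EDL_iii", 0.193, 0.012, 15.69, "ankle"),
    ("FHL_iii", 0.239, 0.020, 11.75, "ankle"),
    ("FL_l", 0.084, 0.049, 1.73, "ankle"),
    ("FL_p", 0.081, 0.049, 1.67, "ankle"),
    ("IG", 0.075, 0.072, 1.05, "ankle"),
    ("LG", 0.102, 0.047, 2.17, "ankle"),
    ("MG_l", 0.105, 0.041, 2.57, "ankle"),
    ("MG_c", 0.118, 0.037, 3.17, "ankle"),
    ("MG_m", 0.120, 0.028, 4.23, "ankle"),
    ("TC_f", 0.119, 0.029, 4.07, "ankle"),
    ("TC_t", 0.072, 0.051, 1.42, "ankle"),
    ("DFii_s", 0.198, 0.013, 15.19, "ankle"),
    ("DFiii_s", 0.183, 0.037, 4.97, "ankle"),
    ("FDL_iii", 0.214, 0.037, 5.78, "ankle"),
]

#: Placeholder maximal isometric force for fixture muscles (not printed).
FIXTURE_FMAX = 30.0


@dataclass(frozen=True)
class JointSpec:
    """Layout of one synthetic joint."""

    moment_arm_range: tuple = (0.005, 0.03)  # m
    reference_angle: float = 0.0             # deg
    angle_range: tuple = (-40.0, 40.0)       # deg
    limb: str = "A"                          # target limb at the reference angle


@dataclass(frozen=True)
class SynthesisSpec:
    """Controls for the random muscle/joint generators; seed-deterministic."""

    n_muscles: int = 40
    tm_ratio_range: tuple = (0.0, 16.55)
    tm_distribution: str = "uniform"         # "uniform" | "bimodal"
    bimodal_centers: tuple = (0.71, 7.82)    # hip-like, ankle-like
    l0_range: tuple = (0.011, 0.12)          # m, span of the reference table
    fmax_range: tuple = (10.0, 100.0)        # N
    pennation_range: tuple = (0.0, 0.0)      # rad
    seed: int = 0
    joint: JointSpec | None = None

    def __post_init__(self) -> None:
        if self.n_muscles < 1:
            raise ValueError("n_muscles must be positive")
        for name in ("tm_ratio_range", "l0_range", "fmax_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-negative interval")
        if self.tm_distribution not in ("uniform", "bimodal"):
            raise ValueError("tm_distribution must be 'uniform' or 'bimodal'")


def table1_fixture() -> list[MuscleParams]:
    """The packaged 39-muscle table (21 hip + 18 ankle), pennation 0.

    Tendon slack lengths and optimal fiber lengths are the published values;
    F100max is a flagged placeholder since the table prints none.
    """
    return [
        MuscleParams(
            name=name,
            tendon_slack_length=tsl,
            optimal_fiber_length=l0,
            pennation_at_optimal=0.0,
            f_max=FIXTURE_FMAX,
            group=group,
            f_max_synthetic=True,
        )
        for name, tsl, l0, _printed, group in TABLE1_ROWS
    ]


def printed_tm_ratios(group: str | None = None) -> np.ndarray:
    """The table's printed T/M ratio column (optionally one group)."""
    return np.array(
        [r[3] for r in TABLE1_ROWS if group is None or r[4] == group]
    )


def _draw_tm(rng: np.random.Generator, spec: SynthesisSpec) -> np.ndarray:
    lo, hi = spec.tm_ratio_range
    if spec.tm_distribution == "uniform":
        return rng.uniform(lo, hi, spec.n_muscles)
    c_low, c_high = spec.bimodal_centers
    n_low = spec.n_muscles // 2
    n_high = spec.n_muscles - n_low
    groups = []
    for center, n in ((c_low, n_low), (c_high, n_high)):
        draws = center * rng.lognormal(mean=0.0, sigma=0.3, size=n)
        draws *= center / draws.mean()  # pin the group mean to its center
        groups.append(draws)
    tm = np.concatenate(groups)
    return np.clip(tm, lo, hi)


def generate_muscles(spec: SynthesisSpec) -> list[MuscleParams]:
    """Random muscle set with the requested T/M ratio structure.

    In bimodal mode the first half is the low-compliance ("hip-like") group
    and the second half the high-compliance ("ankle-like") group, with each
    group's mean T/M pinned to its requested center before range clipping.
    """
    rng = np.random.default_rng(spec.seed)
    tm = _draw_tm(rng, spec)
    l0 = rng.uniform(*spec.l0_range, spec.n_muscles)
    fmax = rng.uniform(*spec.fmax_range, spec.n_muscles)
    penn = rng.uniform(*spec.pennation_range, spec.n_muscles)
    half = spec.n_muscles // 2
    muscles = []
    for i in range(spec.n_muscles):
        if spec.tm_distribution == "bimodal":
            group = "hip-like" if i < half else "ankle-like"
        else:
            group = "synthetic"
        muscles.append(
            MuscleParams(
                name=f"syn{i:03d}",
                tendon_slack_length=float(tm[i] * l0[i]),
                optimal_fiber_length=float(l0[i]),
                pennation_at_optimal=float(penn[i]),
                f_max=float(fmax[i]),
                group=group,
                f_max_synthetic=True,
            )
        )
    return muscles


#: Passive-length target windows per limb class for joint construction.
_LIMB_WINDOWS = {"A": (0.72, 0.90), "P": (0.96, 1.04), "D": (1.15, 1.32)}


def generate_joint_geometry(
    spec: SynthesisSpec,
    muscles: list[MuscleParams],
    curves: CurveSet | None = None,
    joint_name: str = "synthetic_joint",
) -> JointGeometry:
    """Linear MTU-length functions L(theta) = L_ref - r * (theta - theta_ref).

    Each muscle's constant moment arm r is drawn from the spec's range and
    its reference-angle MTU length is placed so the zero-activation fiber
    length falls in the requested limb window.  Deterministic given the
    spec's seed.
    """
    if not muscles:
        raise ValueError("muscles must be non-empty")
    joint = spec.joint or JointSpec()
    curves = curves or CurveSet()
    rng = np.random.default_rng(spec.seed + 1)
    pairs = []
    for m in muscles:
        r = float(rng.uniform(*joint.moment_arm_range))
        target = float(rng.uniform(*_LIMB_WINDOWS[joint.limb]))
        l_ref = mtu_length_for_passive_length(target, m, curves)

        def length_fn(angle_deg, _l_ref=l_ref, _r=r, _ref=joint.reference_angle):
            return _l_ref - _r * math.radians(angle_deg - _ref)

        length_fn.moment_arm = r
        length_fn.passive_target = target
        pairs.append((m, length_fn))
    return JointGeometry(
        joint_name=joint_name,
        muscles=pairs,
        angle_range=joint.angle_range,
        reference_angle=joint.reference_angle,
    )
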