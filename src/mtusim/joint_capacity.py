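"""Joint-level force and moment capacity over a posture sweep.

All muscles spanning a joint are activated at a common submaximal level
(25% by default, a plausible standing effort), their fixed-end equilibria
are solved at the MTU lengths the posture imposes, and the tendon-line
forces are summed into a total force and — through each muscle's moment
arm — a total joint moment.  Moment arms come from the tendon-excursion
(virtual work) relation r = -dL_MTU/dtheta.  The scan locates the postures
maximizing total force and moment and compares a reference (standing)
posture against those maxima.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .muscle_curves import CurveSet
from .mtu_equilibrium import ModelVariant, MuscleParams, solve_equilibrium

__all__ = ["JointGeometry", "JointScanResult", "moment_arm", "joint_scan"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JointGeometry:
    """A joint with its spanning muscles and their MTU-length functions.

    ``muscles`` is a list of ``(MuscleParams, mtu_length_fn)`` pairs where
    ``mtu_length_fn`` maps a joint angle in degrees to MTU length in meters.
    """

    joint_name: str
    muscles: list
    angle_range: tuple  # (min_deg, max_deg)
    reference_angle: float  # deg, the standing posture

    def __post_init__(self) -> None:
        lo, hi = self.angle_range
        if not lo < hi:
            raise ValueError("angle_range must be a non-empty interval")
        if not lo <= self.reference_angle <= hi:
            raise ValueError("reference_angle must lie within angle_range")


@dataclass(frozen=True)
class JointScanResult:
    """Per-angle totals plus the maximizing and reference postures."""

    angles: np.ndarray            # deg
    total_force: np.ndarray       # N
    total_moment: np.ndarray      # N m
    weighted_moment_arm: np.ndarray  # m, F100max-weighted mean
    mean_norm_fiber_length: np.ndarray
    argmax_force_angle: float     # deg
    argmax_moment_angle: float    # deg
    reference_angle: float        # deg
    force_at_reference: float     # N
    moment_at_reference: float    # N m
    pct_diff_force_at_reference: float   # % vs maximum (<= 0)
    pct_diff_moment_at_reference: float  # % vs maximum (<= 0)


def moment_arm(mtu_length_fn, angle_deg: float, step_deg: float = 0.5,
               domain: tuple | None = None) -> float:
    """Moment arm r = -dL/dtheta (theta in radians) by central difference.

    Positive r means the MTU shortens as the angle increases, so positive
    force produces positive moment.  At a domain boundary a one-sided
    difference is used (with a warning).
    """
    step_rad = math.radians(step_deg)
    lo, hi = domain if domain is not None else (-math.inf, math.inf)
    if angle_deg - step_deg >= lo and angle_deg + step_deg <= hi:
        return -(
            mtu_length_fn(angle_deg + step_deg) - mtu_length_fn(angle_deg - step_deg)
        ) / (2.0 * step_rad)
    warnings.warn(
        "moment_arm at a domain boundary: one-sided difference", stacklevel=2
    )
    if angle_deg + step_deg <= hi:
        return -(mtu_length_fn(angle_deg + step_deg) - mtu_length_fn(angle_deg)) / step_rad
    return -(mtu_length_fn(angle_deg) - mtu_length_fn(angle_deg - step_deg)) / step_rad


def joint_scan(
    geometry: JointGeometry,
    activation: float = 0.25,
    variant: ModelVariant = ModelVariant.CS,
    curves: CurveSet | None = None,
    grid_step_deg: float = 2.0,
) -> JointScanResult:
    """Sweep the joint angle and total the muscle forces and moments.

    At each grid angle every muscle's fixed-end equilibrium is solved at
    the MTU length its geometry dictates; slack or non-converged muscles
    contribute zero force.  The F100max-weighted mean moment arm
    characterizes the joint's effective gearing independent of activation.
    """
    if not 0.0 < activation <= 1.0:
        raise ValueError("activation must lie in (0, 1]")
    curves = curves or CurveSet()
    lo, hi = geometry.angle_range
    angles = np.arange(lo, hi + 1e-9, grid_step_deg)

    n = angles.size
    total_force = np.zeros(n)
    total_moment = np.zeros(n)
    weighted_arm = np.zeros(n)
    mean_nfl = np.zeros(n)
    fmax_sum = sum(m.f_max for m, _ in geometry.muscles)

    for i, ang in enumerate(angles):
        arm_acc = 0.0
        nfl_acc = 0.0
        for params, length_fn in geometry.muscles:
            mtu = length_fn(float(ang))
            res = solve_equilibrium(mtu, activation, variant, params, curves)
            r = moment_arm(length_fn, float(ang), domain=geometry.angle_range)
            force = 0.0
            if res.converged and not res.slack:
                force = res.norm_force * params.f_max
            elif not res.converged:
                log.info("muscle %s non-converged at %.1f deg; zero force",
                         params.name, ang)
            total_force[i] += force
            total_moment[i] += force * r
            arm_acc += r * params.f_max
            nfl_acc += res.norm_fiber_length
        weighted_arm[i] = arm_acc / fmax_sum
        mean_nfl[i] = nfl_acc / len(geometry.muscles)

    i_f = int(np.argmax(total_force))
    i_m = int(np.argmax(total_moment))
    i_ref = int(np.argmin(np.abs(angles - geometry.reference_angle)))

    def pct_below_max(value: float, maximum: float) -> float:
        if maximum == 0:
            return 0.0
        return 100.0 * (value - maximum) / maximum

    return JointScanResult(
        angles=angles,
        total_force=total_force,
        total_moment=total_moment,
        weighted_moment_arm=weighted_arm,
        mean_norm_fiber_length=mean_nfl,
        argmax_force_angle=float(angles[i_f]),
        argmax_moment_angle=float(angles[i_m]),
        reference_angle=float(angles[i_ref]),
        force_at_reference=float(total_force[i_ref]),
        moment_at_reference=float(total_moment[i_ref]),
        pct_diff_force_at_reference=pct_below_max(
            float(total_force[i_ref]), float(total_force[i_f])
        ),
        pct_diff_moment_at_reference=pct_below_max(
            float(total_moment[i_ref]), float(total_moment[i_m])
        ),
    )
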