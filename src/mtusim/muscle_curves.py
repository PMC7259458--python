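"""Dimensionless muscle and tendon constitutive curves.

All forces here are normalized by the muscle's maximal isometric force
(F100max) and all fiber lengths by the optimal fiber length at full
activation (L0_100, written L0 below).  Three curves are defined:

* an active force-length (F-L) curve whose optimum can shift to longer
  lengths as activation drops (the "activation-dependent shift" in L0),
* a passive fiber F-L curve that engages above L0, and
* a tendon force-strain curve with a quadratic toe region followed by a
  linear region.

The active curve is a Gaussian bell ``exp(-(L/L0_eff - 1)^2 / w)`` with
effective optimum ``L0_eff = 1 + s * (1 - a)`` for activation ``a`` and
shift fraction ``s`` (default 0.15, i.e. the optimum sits at 1.15 L0 at
zero activation).  The default width ``w`` is calibrated so that the
multiplier at a normalized length of 0.809 equals 0.726, the anchor point
used throughout the force-capacity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurveSet",
    "DEFAULT_ACTIVE_WIDTH",
    "active_multiplier",
    "passive_multiplier",
    "tendon_multiplier",
    "tendon_strain_from_force",
    "effective_optimum",
]

#: Gaussian width such that the active multiplier at L = 0.809 (full
#: activation, no shift) equals 0.726: w = (0.809-1)^2 / (-ln 0.726).
DEFAULT_ACTIVE_WIDTH = (0.809 - 1.0) ** 2 / -math.log(0.726)


@dataclass(frozen=True)
class CurveSet:
    """Parameter bundle for the normalized muscle/tendon curves.

    Parameters
    ----------
    active_width
        Dimensionless shape parameter of the Gaussian active F-L curve.
    passive_strain_at_fmax
        Fiber strain (relative to L0) at which the passive fiber force
        reaches F100max; the passive curve is normalized to 1 there.
    passive_shape
        Exponential shape parameter of the passive curve.
    tendon_strain_at_fmax
        Tendon strain at which tendon force equals F100max (epsilon_0).
    tendon_toe_fraction
        Fraction of epsilon_0 covered by the quadratic toe region.
    shift_fraction
        Fractional increase of the active optimum at zero activation
        (s = 0.15 means the optimum sits at 1.15 L0 when passive).
    """

    active_width: float = DEFAULT_ACTIVE_WIDTH
    passive_strain_at_fmax: float = 0.6
    passive_shape: float = 4.0
    tendon_strain_at_fmax: float = 0.04
    tendon_toe_fraction: float = 0.5
    shift_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "active_width",
            "passive_strain_at_fmax",
            "passive_shape",
            "tendon_strain_at_fmax",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.tendon_toe_fraction < 1.0:
            raise ValueError("tendon_toe_fraction must lie in [0, 1)")
        if self.shift_fraction < 0:
            raise ValueError("shift_fraction must be non-negative")

    # -- tendon toe/linear coefficients -------------------------------
    @property
    def _toe_strain(self) -> float:
        return self.tendon_toe_fraction * self.tendon_strain_at_fmax

    @property
    def _toe_quad(self) -> float:
        """Quadratic coefficient c of the toe region f = c * strain^2."""
        e0, et = self.tendon_strain_at_fmax, self._toe_strain
        if et == 0.0:
            return 0.0
        # continuity of value and slope at the junction plus f(e0) = 1
        return 1.0 / (et * (2.0 * e0 - et))

    @property
    def _linear_stiffness(self) -> float:
        """Slope k of the linear region (matches the toe slope at the junction)."""
        e0, et = self.tendon_strain_at_fmax, self._toe_strain
        if et == 0.0:
            return 1.0 / e0
        return 2.0 * self._toe_quad * et

    @property
    def _toe_force(self) -> float:
        et = self._toe_strain
        return self._toe_quad * et * et


def effective_optimum(activation: float, shift_enabled: bool, curves: CurveSet) -> float:
    """Normalized length of the active curve's optimum, L0_eff.

    Scales linearly from ``1 + shift_fraction`` at zero activation down to
    1 at full activation when the shift is enabled.
    """
    if shift_enabled:
        return 1.0 + curves.shift_fraction * (1.0 - activation)
    return 1.0


def active_multiplier(
    norm_fiber_length,
    activation: float,
    shift_enabled: bool,
    curves: CurveSet,
):
    """Active F-L multiplier in [0, 1]; 1 exactly at the effective optimum.

    Accepts scalars or numpy arrays for ``norm_fiber_length``.
    """
    length = np.asarray(norm_fiber_length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("norm_fiber_length must be strictly positive")
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    l0_eff = effective_optimum(activation, shift_enabled, curves)
    out = np.exp(-((length / l0_eff - 1.0) ** 2) / curves.active_width)
    return float(out) if np.isscalar(norm_fiber_length) else out


def passive_multiplier(norm_fiber_length, curves: CurveSet):
    """Passive fiber F-L multiplier: 0 at or below L0, exponential above.

    Normalized to reach 1 at ``1 + passive_strain_at_fmax``.
    """
    length = np.asarray(norm_fiber_length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("norm_fiber_length must be strictly positive")
    strain = np.clip((length - 1.0) / curves.passive_strain_at_fmax, 0.0, None)
    k = curves.passive_shape
    out = np.expm1(k * strain) / math.expm1(k)
    return float(out) if np.isscalar(norm_fiber_length) else out


def tendon_multiplier(tendon_strain, curves: CurveSet):
    """Normalized tendon force: zero when slack, quadratic toe, then linear."""
    strain = np.asarray(tendon_strain, dtype=float)
    et = curves._toe_strain
    c = curves._toe_quad
    k = curves._linear_stiffness
    toe = c * strain * strain
    lin = curves._toe_force + k * (strain - et)
    out = np.where(strain <= 0.0, 0.0, np.where(strain <= et, toe, lin))
    return float(out) if np.isscalar(tendon_strain) else out


def tendon_strain_from_force(norm_force, curves: CurveSet):
    """Exact inverse of :func:`tendon_multiplier` on forces >= 0."""
    force = np.asarray(norm_force, dtype=float)
    if np.any(force < 0):
        raise ValueError("norm_force must be non-negative")
    et = curves._toe_strain
    c = curves._toe_quad
    k = curves._linear_stiffness
    ft = curves._toe_force
    with np.errstate(divide="ignore", invalid="ignore"):
        toe_inv = np.sqrt(force / c) if c > 0 else np.zeros_like(force)
    lin_inv = et + (force - ft) / k
    out = np.where(force <= ft, toe_inv, lin_inv)
    out = np.where(force == 0.0, 0.0, out)
    return float(out) if np.isscalar(norm_force) else out
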