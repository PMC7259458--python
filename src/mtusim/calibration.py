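"""Muscle parameter derivation from architecture measurements.

Implements the standard chain from dissection measurements to model
parameters:

* optimal fiber length from fascicle and sarcomere length
  (``L0 = Lf * 2.36 / Ls``, 2.36 um being the optimal sarcomere length in
  guinea fowl muscle),
* cross-sectional area and maximal isometric force from muscle mass
  (``CSA = m / (rho * L0)`` with rho = 1060 kg/m^3, ``F100max = sigma * CSA``
  with specific tension sigma = 3e5 N/m^2), and
* tendon slack length from the requirement that the model's passive fiber
  length match the measured fiber length at the digitized posture:

  ``MTU_model - Lm * cos(theta) - TSL * (1 + eps(Fp)) = 0``

  where ``Fp = f_pas(Lm / L0) * cos(theta)`` is the normalized passive
  fiber force along the tendon and ``eps`` the inverse tendon force-strain
  curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .muscle_curves import (
    CurveSet,
    passive_multiplier,
    tendon_strain_from_force,
)

__all__ = [
    "ArchitectureMeasurement",
    "OPTIMAL_SARCOMERE_UM",
    "MUSCLE_DENSITY",
    "SPECIFIC_TENSION",
    "optimal_fiber_length",
    "csa_and_fmax",
    "solve_tendon_slack_length",
]

OPTIMAL_SARCOMERE_UM = 2.36   # um, optimal sarcomere length (guinea fowl)
MUSCLE_DENSITY = 1060.0       # kg/m^3
SPECIFIC_TENSION = 3e5        # N/m^2


@dataclass(frozen=True)
class ArchitectureMeasurement:
    """One muscle's dissection measurements (SI units; sarcomeres in um)."""

    fascicle_length: float      # m, measured fiber length Lm at the posture
    sarcomere_length: float     # um
    muscle_mass: float          # kg
    pennation_measured: float   # rad
    mtu_length_model: float     # m, MTU length from the geometric model

    def __post_init__(self) -> None:
        for name in (
            "fascicle_length",
            "sarcomere_length",
            "muscle_mass",
            "mtu_length_model",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 1.0 <= self.sarcomere_length <= 4.5:
            warnings.warn(
                "sarcomere_length outside the physiological 1.0-4.5 um range",
                stacklevel=2,
            )


def optimal_fiber_length(fascicle_length: float, sarcomere_length: float) -> float:
    """L0 in meters from fascicle length (m) and sarcomere length (um)."""
    if fascicle_length <= 0 or sarcomere_length <= 0:
        raise ValueError("lengths must be strictly positive")
    return fascicle_length * OPTIMAL_SARCOMERE_UM / sarcomere_length


def csa_and_fmax(muscle_mass: float, optimal_fiber_length_m: float):
    """Cross-sectional area (m^2) and maximal isometric force (N)."""
    if muscle_mass <= 0 or optimal_fiber_length_m <= 0:
        raise ValueError("inputs must be strictly positive")
    csa = muscle_mass / (MUSCLE_DENSITY * optimal_fiber_length_m)
    return csa, SPECIFIC_TENSION * csa


def solve_tendon_slack_length(
    measurement: ArchitectureMeasurement,
    f_max: float,
    curves: CurveSet,
    tolerance: float = 1e-12,
) -> float:
    """Tendon slack length consistent with the measured passive fiber state.

    The passive fiber force (hence the tendon strain) depends only on the
    measured fiber length, so the root equation is monotone in TSL and the
    bracketed solve on ``(0, MTU_model - Lm cos theta]`` cannot miss.
    ``f_max`` is accepted for interface symmetry with the normalized curves.
    """
    lm = measurement.fascicle_length
    theta = measurement.pennation_measured
    l0 = optimal_fiber_length(lm, measurement.sarcomere_length)
    cos_t = math.cos(theta)
    fiber_span = lm * cos_t
    mtu = measurement.mtu_length_model
    if mtu <= fiber_span:
        raise ValueError(
            "mtu_length_model must exceed the fiber's projection on the tendon"
        )
    fp = passive_multiplier(lm / l0, curves) * cos_t
    strain = tendon_strain_from_force(fp, curves)

    def residual(tsl: float) -> float:
        return mtu - fiber_span - tsl * (1.0 + strain)

    upper = mtu - fiber_span
    if strain == 0.0:
        return upper  # slack fiber: the tendon carries no stretch
    lo = min(1e-15, upper * 1e-9)
    if residual(upper) > 0:
        raise ValueError("no tendon slack length satisfies the measurement")
    return brentq(residual, lo, upper, xtol=tolerance, rtol=8.9e-16)
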