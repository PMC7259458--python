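"""Fixed-end muscle-tendon equilibrium.

A muscle-tendon unit (MTU) held at constant total length reaches a static
balance between the fiber force resolved along the tendon and the tendon
force.  With fiber lengths normalized by the optimal fiber length at full
activation (L0) and forces by F100max, the balance reads::

    (a * f_act(L) + f_pas(L)) * cos(theta(L)) = f_ten(eps(L))

where ``a`` is activation, ``theta`` the pennation angle under the
fixed-width assumption (L * sin(theta) constant), and
``eps = (MTU - L * cos(theta) * L0 - TSL) / TSL`` the tendon strain for
tendon slack length TSL.

Three model variants are supported:

* ``NCNS`` - rigid tendon (fixed at slack length), no shift of the active
  optimum with activation;
* ``CNS``  - compliant tendon, no shift;
* ``CS``   - compliant tendon plus an activation-dependent shift of the
  optimum (15% longer at zero activation by default).

The solver parameterizes the balance by fiber length: the muscle force at a
candidate length determines the tendon strain through the inverse tendon
curve, hence an implied MTU length; the equilibrium fiber length is the
root of ``implied MTU length - actual MTU length``.  When several roots
exist (possible on the descending limb with a slack-adjacent tendon) the
longest root is taken, i.e. the state continuously connected to the passive
state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .muscle_curves import CurveSet, effective_optimum

__all__ = [
    "MuscleParams",
    "ModelVariant",
    "EquilibriumResult",
    "rigid_fiber_length",
    "solve_equilibrium",
    "delta_length",
    "mtu_length_for_passive_length",
]

#: Normalized fiber-length search interval (in units of L0_eff).
SEARCH_INTERVAL = (0.01, 1.9)
#: Default normalized force-residual tolerance for a converged solve.
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class MuscleParams:
    """Architecture of one muscle-tendon actuator.

    Lengths in meters, forces in newtons, pennation in radians.
    ``tm_ratio`` (tendon slack length over optimal fiber length) is the
    compliance index used throughout the analyses.
    """

    name: str
    tendon_slack_length: float
    optimal_fiber_length: float
    pennation_at_optimal: float = 0.0
    f_max: float = 30.0
    group: str = "synthetic"
    f_max_synthetic: bool = False

    def __post_init__(self) -> None:
        if self.optimal_fiber_length <= 0:
            raise ValueError("optimal_fiber_length must be positive")
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if self.tendon_slack_length < 0:
            raise ValueError("tendon_slack_length must be non-negative")
        if not 0.0 <= self.pennation_at_optimal < math.pi / 2:
            raise ValueError("pennation_at_optimal must lie in [0, pi/2)")

    @property
    def tm_ratio(self) -> float:
        return self.tendon_slack_length / self.optimal_fiber_length


class ModelVariant(str, enum.Enum):
    """Muscle model variant: tendon compliance x activation-dependent shift."""

    NCNS = "NCNS"  # rigid tendon, no shift
    CNS = "CNS"    # compliant tendon, no shift
    CS = "CS"      # compliant tendon, 15% shift at zero activation

    @property
    def compliant(self) -> bool:
        return self is not ModelVariant.NCNS

    @property
    def shifted(self) -> bool:
        return self is ModelVariant.CS


@dataclass(frozen=True)
class EquilibriumResult:
    """Solved fixed-end state, normalized by L0 (length) and F100max (force).

    ``norm_force`` is the active fiber force resolved along the tendon line;
    the passive fiber force participates in the balance but is not part of
    the reported force capacity.
    """

    norm_fiber_length: float
    pennation: float
    tendon_strain: float
    norm_force: float
    residual: float
    converged: bool
    slack: bool = False


# ---------------------------------------------------------------------------
# fast scalar curve evaluations (closed forms shared with muscle_curves)
# ---------------------------------------------------------------------------

def _active_scalar(length: float, l0_eff: float, width: float) -> float:
    z = length / l0_eff - 1.0
    return math.exp(-z * z / width)


def _passive_scalar(length: float, curves: CurveSet) -> float:
    if length <= 1.0:
        return 0.0
    q = (length - 1.0) / curves.passive_strain_at_fmax
    k = curves.passive_shape
    return math.expm1(k * q) / math.expm1(k)


def _strain_from_force_scalar(force: float, curves: CurveSet) -> float:
    if force <= 0.0:
        return 0.0
    ft = curves._toe_force
    if force <= ft:
        return math.sqrt(force / curves._toe_quad)
    return curves._toe_strain + (force - ft) / curves._linear_stiffness


def _tendon_scalar(strain: float, curves: CurveSet) -> float:
    if strain <= 0.0:
        return 0.0
    et = curves._toe_strain
    if strain <= et:
        return curves._toe_quad * strain * strain
    return curves._toe_force + curves._linear_stiffness * (strain - et)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _pennation_at(norm_length: float, params: MuscleParams) -> float:
    """Pennation under the fixed-width model; norm_length relative to L0."""
    sin0 = math.sin(params.pennation_at_optimal)
    if sin0 == 0.0:
        return 0.0
    return math.asin(min(sin0 / norm_length, 1.0))


def rigid_fiber_length(mtu_length: float, params: MuscleParams):
    """Fiber length and pennation with the tendon fixed at slack length.

    Returns ``(norm_fiber_length, pennation, slack)``; ``slack`` is True
    when the MTU is shorter than the slack tendon plus the fiber's fixed
    width, in which case the geometry is degenerate and the returned length
    is clipped at the search floor.
    """
    l0 = params.optimal_fiber_length
    w = l0 * math.sin(params.pennation_at_optimal)
    proj = mtu_length - params.tendon_slack_length
    if proj <= 0.0:
        if w > 0.0:
            return w / l0, math.pi / 2 * 0.999, True
        return SEARCH_INTERVAL[0], 0.0, True
    fiber = math.hypot(w, proj)
    return fiber / l0, math.atan2(w, proj), False


def _result_at_length(
    norm_length: float,
    mtu_length: float,
    activation: float,
    variant: ModelVariant,
    params: MuscleParams,
    curves: CurveSet,
    slack: bool,
    converged: bool = True,
) -> EquilibriumResult:
    l0 = params.optimal_fiber_length
    theta = _pennation_at(norm_length, params)
    cos_t = math.cos(theta)
    l0_eff = effective_optimum(activation, variant.shifted, curves)
    f_active = activation * _active_scalar(norm_length, l0_eff, curves.active_width)
    f_passive = _passive_scalar(norm_length, curves)
    along_tendon = (f_active + f_passive) * cos_t
    tsl = params.tendon_slack_length
    if variant.compliant and tsl > 0.0 and not slack:
        strain = (mtu_length - norm_length * l0 * cos_t - tsl) / tsl
        residual = along_tendon - _tendon_scalar(strain, curves)
    else:
        strain = 0.0
        residual = 0.0
    if slack:
        f_active = 0.0
    return EquilibriumResult(
        norm_fiber_length=norm_length,
        pennation=theta,
        tendon_strain=strain,
        norm_force=f_active * cos_t,
        residual=residual,
        converged=converged and abs(residual) <= RESIDUAL_TOL,
        slack=slack,
    )


def solve_equilibrium(
    mtu_length: float,
    activation: float,
    variant: ModelVariant,
    params: MuscleParams,
    curves: CurveSet,
    tolerance: float = RESIDUAL_TOL,
) -> EquilibriumResult:
    """Solve the fixed-end force balance for one condition.

    For the rigid-tendon variant (and for zero-length tendons, which cannot
    stretch) the fiber length follows from geometry alone and only the force
    depends on activation.  For compliant variants the balance is solved by
    bracketed root finding on the implied-MTU-length residual; among
    multiple sign changes the longest (most passive-like) root is taken.
    """
    if mtu_length <= 0:
        raise ValueError("mtu_length must be positive")
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")

    tsl = params.tendon_slack_length
    l0 = params.optimal_fiber_length

    # Rigid geometry: NCNS always; compliant variants when the tendon has
    # zero length (nothing to stretch).
    if not variant.compliant or tsl == 0.0:
        norm_len, theta, slack = rigid_fiber_length(mtu_length, params)
        return _result_at_length(
            norm_len, mtu_length, activation, variant, params, curves, slack
        )

    l0_eff = effective_optimum(activation, variant.shifted, curves)
    sin0 = math.sin(params.pennation_at_optimal)
    width = curves.active_width

    def implied_mtu_minus_actual(norm_len: float) -> float:
        cos_t = math.sqrt(max(norm_len * norm_len - sin0 * sin0, 0.0)) / norm_len
        force = (
            activation * _active_scalar(norm_len, l0_eff, width)
            + _passive_scalar(norm_len, curves)
        ) * cos_t
        strain = _strain_from_force_scalar(force, curves)
        return norm_len * cos_t * l0 + tsl * (1.0 + strain) - mtu_length

    # Zero active drive with a slack-capable passive state: the fiber rests
    # where the tendon is exactly at slack length (the rigid geometry),
    # avoiding the zero-force equilibrium continuum.
    if activation == 0.0:
        norm_len, theta, slack = rigid_fiber_length(mtu_length, params)
        if slack or norm_len <= 1.0:
            return _result_at_length(
                norm_len, mtu_length, 0.0, variant, params, curves, slack
            )

    lo = max(SEARCH_INTERVAL[0] * l0_eff, sin0 + 1e-9)
    hi = SEARCH_INTERVAL[1] * l0_eff
    grid = np.linspace(lo, hi, 257)
    vals = np.array([implied_mtu_minus_actual(x) for x in grid])

    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    exact = np.nonzero(vals == 0.0)[0]
    if exact.size and (not sign_change.size or exact[-1] > sign_change[-1]):
        root = float(grid[exact[-1]])
    elif sign_change.size:
        i = sign_change[-1]
        root = brentq(
            implied_mtu_minus_actual,
            grid[i],
            grid[i + 1],
            xtol=1e-14,
            rtol=8.9e-16,
        )
    else:
        if np.all(vals > 0):
            # MTU shorter than any force-bearing configuration: fully slack.
            return _result_at_length(
                lo, mtu_length, activation, variant, params, curves,
                slack=True,
            )
        return _result_at_length(
            float(grid[int(np.argmin(np.abs(vals)))]),
            mtu_length, activation, variant, params, curves,
            slack=False, converged=False,
        )

    return _result_at_length(
        float(root), mtu_length, activation, variant, params, curves, slack=False
    )


def delta_length(length_at_a: float, length_at_zero: float) -> float:
    """Fiber-length change with activation, dL = L_a - L_0 (units of L0)."""
    return length_at_a - length_at_zero


def mtu_length_for_passive_length(
    target_norm_length: float, params: MuscleParams, curves: CurveSet
) -> float:
    """MTU length whose zero-activation equilibrium fiber length is the target.

    Closed form: the passive fiber force at the target length fixes the
    tendon strain through the inverse tendon curve.  Shift and variant are
    irrelevant at zero activation.
    """
    if target_norm_length <= 0:
        raise ValueError("target_norm_length must be positive")
    l0 = params.optimal_fiber_length
    sin0 = math.sin(params.pennation_at_optimal)
    if target_norm_length <= sin0:
        raise ValueError("target length below the fixed-width pennation floor")
    cos_t = math.sqrt(target_norm_length**2 - sin0**2) / target_norm_length
    force = _passive_scalar(target_norm_length, curves) * cos_t
    strain = _strain_from_force_scalar(force, curves)
    return target_norm_length * l0 * cos_t + params.tendon_slack_length * (1.0 + strain)
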