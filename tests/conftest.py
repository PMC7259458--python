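import numpy as np
import pytest

from mtusim import CurveSet, SweepConfig, build_condition_grid, run_sweep, table1_fixture


@pytest.fixture(scope="session")
def curves():
    return CurveSet()


@pytest.fixture(scope="session")
def fixture_muscles():
    return table1_fixture()


@pytest.fixture(scope="session")
def fixture_sweep(fixture_muscles, curves):
    """The full default sweep over the packaged 39-muscle table
    (3 variants x 5 activations x 80 passive lengths per muscle)."""
    conditions = build_condition_grid(fixture_muscles, SweepConfig(), curves)
    return run_sweep(conditions, curves)


def grid_scan_equilibrium(mtu_length, activation, params, curves, shifted,
                          step=1e-6):
    """Independent brute-force oracle for the fixed-end balance.

    Evaluates the force imbalance
    (a*f_act + f_pas)*cos(theta) - f_ten(strain) on a fine fiber-length
    grid using the public curve functions and returns the midpoint of the
    rightmost sign-change interval (the longest root).
    """
    from mtusim.muscle_curves import (
        effective_optimum, passive_multiplier, tendon_multiplier,
    )
    import mtusim.muscle_curves as mc

    l0 = params.optimal_fiber_length
    tsl = params.tendon_slack_length
    sin0 = np.sin(params.pennation_at_optimal)
    l0_eff = effective_optimum(activation, shifted, curves)
    lengths = np.arange(max(0.01 * l0_eff, sin0 + 1e-6), 1.9 * l0_eff, step)
    cos_t = np.sqrt(lengths**2 - sin0**2) / lengths
    active = mc.active_multiplier(lengths, activation, shifted, curves)
    passive = passive_multiplier(lengths, curves)
    strain = (mtu_length - lengths * l0 * cos_t - tsl) / tsl
    imbalance = (activation * active + passive) * cos_t - tendon_multiplier(
        strain, curves
    )
    sign = np.sign(imbalance)
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if change.size == 0:
        return None
    i = change[-1]
    return float(lengths[i] + lengths[i + 1]) / 2.0
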