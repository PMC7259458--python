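"""Fixed-end equilibrium solver: geometry, oracle agreement, physics."""

import math

import numpy as np
import pytest

from mtusim import (
    CurveSet,
    ModelVariant,
    MuscleParams,
    delta_length,
    mtu_length_for_passive_length,
    rigid_fiber_length,
    solve_equilibrium,
)

from conftest import grid_scan_equilibrium


def make_muscle(tsl=0.10, l0=0.05, penn_deg=0.0, name="m"):
    return MuscleParams(
        name=name,
        tendon_slack_length=tsl,
        optimal_fiber_length=l0,
        pennation_at_optimal=math.radians(penn_deg),
    )


class TestRigidGeometry:
    def test_parallel_fibered(self):
        norm, theta, slack = rigid_fiber_length(0.14, make_muscle())
        assert norm == pytest.approx(0.8)
        assert theta == 0.0
        assert not slack

    def test_identity_posture_any_pennation(self):
        for deg in (0.0, 10.0, 20.0, 40.0):
            m = make_muscle(penn_deg=deg)
            mtu = m.tendon_slack_length + m.optimal_fiber_length * math.cos(
                m.pennation_at_optimal
            )
            norm, theta, slack = rigid_fiber_length(mtu, m)
            assert norm == pytest.approx(1.0, abs=1e-12)
            assert theta == pytest.approx(m.pennation_at_optimal, abs=1e-12)

    def test_pennated_geometry_hand_trig(self):
        # fixed width w = L0 sin(20 deg); fiber = hypot(w, MTU - TSL)
        m = make_muscle(penn_deg=20.0)
        norm, theta, _ = rigid_fiber_length(0.14, m)
        w = 0.05 * math.sin(math.radians(20.0))
        assert norm == pytest.approx(math.hypot(w, 0.04) / 0.05, abs=1e-12)
        assert theta == pytest.approx(math.atan2(w, 0.04), abs=1e-12)

    def test_slack_mtu_flagged(self):
        norm, _, slack = rigid_fiber_length(0.09, make_muscle())
        assert slack


class TestSolveEquilibrium:
    def test_zero_activation_short_passive_state(self, curves):
        # passive length below L0: slack fiber, slack tendon, zero force
        m = make_muscle()
        mtu = mtu_length_for_passive_length(0.9, m, curves)
        res = solve_equilibrium(mtu, 0.0, ModelVariant.CNS, m, curves)
        assert res.norm_force == 0.0
        assert res.tendon_strain == pytest.approx(0.0, abs=1e-15)
        assert res.norm_fiber_length == pytest.approx(0.9, abs=1e-12)

    def test_zero_tendon_matches_rigid_at_any_activation(self, curves):
        m = make_muscle(tsl=0.0, l0=0.08)
        for a in (0.0, 0.25, 0.5, 1.0):
            for variant in (ModelVariant.CNS, ModelVariant.CS):
                compliant = solve_equilibrium(0.07, a, variant, m, curves)
                rigid = solve_equilibrium(0.07, a, ModelVariant.NCNS, m, curves)
                assert compliant.norm_fiber_length == rigid.norm_fiber_length

    def test_solver_matches_grid_scan_oracle(self, curves):
        # brute-force zero-crossing scan at 1e-6 resolution, high-compliance
        m = make_muscle(tsl=0.25, l0=0.05)  # T/M = 5
        mtu = mtu_length_for_passive_length(1.0, m, curves)
        res = solve_equilibrium(mtu, 1.0, ModelVariant.CNS, m, curves)
        oracle = grid_scan_equilibrium(mtu, 1.0, m, curves, shifted=False)
        assert res.norm_fiber_length == pytest.approx(oracle, abs=1e-5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_oracle_agreement_random_conditions(self, curves, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            m = make_muscle(
                tsl=float(rng.uniform(0.01, 0.3)),
                l0=float(rng.uniform(0.02, 0.1)),
                penn_deg=float(rng.uniform(0.0, 25.0)),
            )
            a = float(rng.uniform(0.05, 1.0))
            target = float(rng.uniform(0.6, 1.4))
            variant = ModelVariant.CS if rng.random() < 0.5 else ModelVariant.CNS
            mtu = mtu_length_for_passive_length(target, m, curves)
            res = solve_equilibrium(mtu, a, variant, m, curves)
            oracle = grid_scan_equilibrium(
                mtu, a, m, curves, shifted=variant.shifted
            )
            assert oracle is not None
            assert res.norm_fiber_length == pytest.approx(oracle, abs=1e-5)

    def test_residual_contract(self, curves):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = make_muscle(
                tsl=float(rng.uniform(0.0, 0.3)),
                l0=float(rng.uniform(0.02, 0.1)),
            )
            mtu = mtu_length_for_passive_length(float(rng.uniform(0.6, 1.4)), m, curves)
            res = solve_equilibrium(
                mtu, float(rng.uniform(0.0, 1.0)),
                ModelVariant.CNS, m, curves,
            )
            assert res.converged
            assert abs(res.residual) <= 1e-9

    def test_rigid_length_activation_invariant(self, curves):
        m = make_muscle()
        lengths = {
            solve_equilibrium(0.145, a, ModelVariant.NCNS, m, curves).norm_fiber_length
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
        }
        assert len(lengths) == 1

    def test_activation_monotonically_shortens_ascending_fiber(self, curves):
        m = make_muscle(tsl=0.15, l0=0.05)
        mtu = mtu_length_for_passive_length(0.9, m, curves)
        lengths = [
            solve_equilibrium(mtu, a, ModelVariant.CNS, m, curves).norm_fiber_length
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b <= a_ for a_, b in zip(lengths, lengths[1:]))

    def test_shortening_monotone_in_compliance(self, curves):
        # same passive length, same activation: more tendon => more shortening
        shortenings = []
        for tm in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0):
            m = make_muscle(tsl=tm * 0.05, l0=0.05)
            mtu = mtu_length_for_passive_length(0.9, m, curves)
            res = solve_equilibrium(mtu, 0.75, ModelVariant.CNS, m, curves)
            shortenings.append(0.9 - res.norm_fiber_length)
        assert all(b >= a - 1e-12 for a, b in zip(shortenings, shortenings[1:]))

    def test_cs_equals_cns_at_full_activation(self, curves):
        m = make_muscle(tsl=0.2, l0=0.04)
        mtu = mtu_length_for_passive_length(1.1, m, curves)
        cns = solve_equilibrium(mtu, 1.0, ModelVariant.CNS, m, curves)
        cs = solve_equilibrium(mtu, 1.0, ModelVariant.CS, m, curves)
        assert abs(cs.norm_fiber_length - cns.norm_fiber_length) <= 1e-12
        assert abs(cs.norm_force - cns.norm_force) <= 1e-12

    def test_input_validation(self, curves):
        m = make_muscle()
        with pytest.raises(ValueError):
            solve_equilibrium(-0.1, 0.5, ModelVariant.CNS, m, curves)
        with pytest.raises(ValueError):
            solve_equilibrium(0.14, 1.5, ModelVariant.CNS, m, curves)


class TestDeltaLength:
    def test_subtraction_and_identity(self):
        assert delta_length(0.92, 1.00) == pytest.approx(-0.08)
        assert delta_length(0.75, 0.75) == 0.0

    def test_rigid_variant_never_changes_length(self, curves):
        m = make_muscle()
        ref = solve_equilibrium(0.145, 0.0, ModelVariant.NCNS, m, curves)
        for a in (0.25, 0.5, 0.75, 1.0):
            res = solve_equilibrium(0.145, a, ModelVariant.NCNS, m, curves)
            assert delta_length(res.norm_fiber_length, ref.norm_fiber_length) == 0.0


class TestPassiveInverse:
    def test_round_trip_through_solver(self, curves):
        rng = np.random.default_rng(11)
        for _ in range(30):
            m = make_muscle(
                tsl=float(rng.uniform(0.0, 0.25)),
                l0=float(rng.uniform(0.02, 0.1)),
                penn_deg=float(rng.uniform(0.0, 20.0)),
            )
            target = float(rng.uniform(0.6, 1.4))
            mtu = mtu_length_for_passive_length(target, m, curves)
            res = solve_equilibrium(mtu, 0.0, ModelVariant.CNS, m, curves)
            assert res.norm_fiber_length == pytest.approx(target, abs=1e-9)
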