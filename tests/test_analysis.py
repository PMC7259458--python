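"""Binned statistics: limb classes, relative force changes, sensitivity maps."""

import numpy as np
import pandas as pd
import pytest

from mtusim import (
    classify_limb,
    group_summaries,
    ncns_force,
    pair_variants,
    percent_delta_force,
    sensitivity_map,
    shift_contribution,
)


class TestClassifyLimb:
    @pytest.mark.parametrize(
        "length,expected",
        [(0.80, "A"), (1.00, "P"), (1.30, "D"), (0.95, "P"), (1.05, "P")],
    )
    def test_default_plateau_convention(self, length, expected):
        assert classify_limb(length) == expected

    def test_positive_length_required(self):
        with pytest.raises(ValueError):
            classify_limb(0.0)


class TestScalarStatistics:
    def test_rigid_force_scales_linearly_with_activation(self):
        # the worked half-activation example: 0.5 x 0.726 = 0.363
        assert ncns_force(0.5, 0.726) == pytest.approx(0.363, abs=1e-15)
        assert ncns_force(1.0, 0.61) == 0.61
        assert ncns_force(0.0, 0.9) == 0.0

    def test_shift_contribution_is_a_length_difference(self):
        assert shift_contribution(0.98, 1.00) == pytest.approx(-0.02)
        assert shift_contribution(0.5, 0.5) == 0.0

    @pytest.mark.parametrize(
        "fc,fs,expected", [(0.5, 0.4, 25.0), (0.4, 0.4, 0.0), (0.2, 0.4, -50.0)]
    )
    def test_percent_delta_force(self, fc, fs, expected):
        assert percent_delta_force(fc, fs) == pytest.approx(expected)

    def test_percent_delta_force_undefined_near_zero(self):
        with pytest.raises(ValueError):
            percent_delta_force(0.5, 0.0)


def toy_table():
    """Two muscles x two variants x two activations, hand-sized numbers."""
    rows = []
    for muscle, tm, lengths in (
        ("a", 0.5, (0.80, 0.84)),
        ("b", 4.0, (1.20, 1.10)),
    ):
        for variant in ("NCNS", "CNS"):
            for activation, mtu, eq, force in (
                (0.0, 1.0, lengths[0], 0.0),
                (0.5, 1.0, lengths[1] if variant == "CNS" else lengths[0], 0.4),
            ):
                rows.append(
                    {
                        "muscle": muscle,
                        "group": "toy",
                        "variant": variant,
                        "activation": activation,
                        "mtu_length": mtu,
                        "eq_norm_length": eq,
                        "norm_force": force,
                        "tendon_strain": 0.0,
                        "tm_ratio": tm,
                        "passive_norm_length": lengths[0],
                        "limb": classify_limb(lengths[0]),
                    }
                )
    return pd.DataFrame(rows)


class TestGroupSummaries:
    def test_single_record_group_mean_equals_record(self):
        out = group_summaries(toy_table())
        cell = out[
            (out["compliance_class"] == "Low")
            & (out["variant"] == "CNS")
            & (out["activation"] == 0.5)
        ].iloc[0]
        assert cell["limb"] == "A"
        assert cell["n"] == 1
        assert cell["mean_norm_length"] == pytest.approx(0.84)
        assert cell["mean_delta_length"] == pytest.approx(0.04)

    def test_rigid_groups_have_zero_mean_delta(self):
        out = group_summaries(toy_table())
        ncns = out[out["variant"] == "NCNS"]
        assert (ncns["mean_delta_length"] == 0).all()

    def test_two_record_group_hand_average(self, fixture_sweep):
        sub = fixture_sweep[
            (fixture_sweep["muscle"].isin(["LG", "MG_l"]))
            & (fixture_sweep["variant"] == "CNS")
            & (fixture_sweep["activation"] == 0.5)
        ]
        pick = sub.groupby("muscle").head(1)  # one record per muscle
        out = group_summaries(pick)
        assert len(out) == 1
        assert out.iloc[0]["mean_norm_force"] == pytest.approx(
            pick["norm_force"].mean()
        )

    def test_groups_partition_all_records(self, fixture_sweep):
        out = group_summaries(fixture_sweep)
        assert out["n"].sum() == len(fixture_sweep)


class TestSensitivityMap:
    def test_identical_forces_give_zero_fractions(self):
        t = toy_table()
        t.loc[t["variant"] == "CNS", "eq_norm_length"] = list(
            t.loc[t["variant"] == "NCNS", "eq_norm_length"]
        )
        bins = sensitivity_map(t, ("NCNS", "CNS"), activation=0.5)
        assert (bins["frac_exceeding"] == 0).all()

    def test_hand_built_bin_fraction(self):
        # six matched records in one bin: three above, three below threshold
        rows = []
        for i, fc in enumerate([0.5, 0.48, 0.46, 0.401, 0.42, 0.43]):
            for variant, force in (("NCNS", 0.4), ("CNS", fc)):
                rows.append(
                    {
                        "muscle": f"m{i}",
                        "group": "toy",
                        "variant": variant,
                        "activation": 0.25,
                        "mtu_length": 1.0,
                        "eq_norm_length": 0.9,
                        "norm_force": force,
                        "tendon_strain": 0.0,
                        "tm_ratio": 0.5,
                        "passive_norm_length": 0.91,
                        "limb": "A",
                    }
                )
        bins = sensitivity_map(pd.DataFrame(rows), ("NCNS", "CNS"), 0.25)
        assert len(bins) == 1
        assert bins.iloc[0]["n_samples"] == 6
        assert bins.iloc[0]["frac_exceeding"] == pytest.approx(0.5)

    def test_bin_accounting(self, fixture_sweep):
        pairs = pair_variants(fixture_sweep, "NCNS", "CNS", activation=0.25)
        bins = sensitivity_map(fixture_sweep, ("NCNS", "CNS"), activation=0.25)
        assert bins["n_samples"].sum() + bins.attrs["n_excluded"] == len(pairs)

    def test_nonuniform_tm_bin_edges(self, fixture_sweep):
        bins = sensitivity_map(fixture_sweep, ("NCNS", "CNS"), activation=0.25)
        low = bins[bins["tm_hi"] <= 2.0]
        high = bins[bins["tm_lo"] >= 2.0]
        assert np.allclose(low["tm_hi"] - low["tm_lo"], 0.2)
        assert np.allclose(high["tm_hi"] - high["tm_lo"], 1.0)

    def test_zero_tendon_muscles_have_zero_compliance_effect(self, fixture_sweep):
        pairs = pair_variants(fixture_sweep, "NCNS", "CNS")
        zt = pairs[pairs["tm_ratio_simple"] == 0].dropna(
            subset=["pct_delta_force"]
        )
        assert len(zt) > 0
        assert (zt["pct_delta_force"] == 0).all()
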