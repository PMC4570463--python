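"""Batch setup, unit conversions, SMP and the response-surface sweep."""

import numpy as np
import pytest

from lcfad import (
    NS1,
    NS2,
    BatchConfig,
    InoculumSpec,
    MethaneCurve,
    SubstrateSpec,
    calcium_equivalent,
    initial_state,
    methane_curve,
    potential_lcfa,
    simulate_batch,
    smp,
    sweep,
)


class TestPotentialLcfa:
    def test_reference_substrates_match_measured_concentrations(self):
        """The LCFA pools measured in the two digesters: 9.9 and 3.1 g COD/L
        at 10 gVS/L loading."""
        config = BatchConfig()
        assert potential_lcfa(NS1, config) == pytest.approx(9.9, abs=0.05)
        assert potential_lcfa(NS2, config) == pytest.approx(3.1, abs=0.05)

    def test_zero_lcfa_fraction(self):
        sub = SubstrateSpec("lean", 0, 20, 30, 50, 90, f_fa=0.0)
        assert potential_lcfa(sub, BatchConfig()) == 0.0

    @pytest.mark.parametrize("factor", [0.5, 2.0, 3.7])
    def test_linear_in_loading_and_fraction(self, factor):
        config = BatchConfig()
        base = potential_lcfa(NS1, config)
        scaled_load = BatchConfig(loading_gvs_l=10.0 * factor)
        assert potential_lcfa(NS1, scaled_load) == pytest.approx(base * factor)
        import dataclasses
        sub = dataclasses.replace(NS2, f_fa=NS2.f_fa * 2)
        assert potential_lcfa(sub, config) == pytest.approx(
            2 * potential_lcfa(NS2, config))


class TestCalciumEquivalent:
    def test_one_calcium_binds_two_lcfa(self):
        # a 0.5 mol/mol dose exactly covers the LCFA pool
        assert calcium_equivalent(0.5, 9.9) == pytest.approx(9.9)
        assert calcium_equivalent(2.0, 3.1) == pytest.approx(12.4)
        assert calcium_equivalent(0.0, 9.9) == 0.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            calcium_equivalent(-0.5, 9.9)


class TestInitialState:
    def test_no_inoculum_means_no_biomass(self, inoculum):
        state = initial_state(NS1, inoculum, BatchConfig(is_ratio=0.0))
        assert state.X_h == state.X_v == state.X_m == 0.0
        assert state.S_p == pytest.approx(28.3)

    def test_equal_split_arithmetic(self):
        inoc = InoculumSpec(split=(1 / 3, 1 / 3, 1 / 3))
        state = initial_state(NS1, inoc, BatchConfig(is_ratio=1.0))
        # 1.0 * 10 gVS/L * 1.42 gCOD/gVS / 3
        for x in (state.X_h, state.X_v, state.X_m):
            assert x == pytest.approx(4.7333333, abs=1e-6)

    def test_calcium_dose_enters_as_equivalent(self, inoculum):
        state = initial_state(NS1, inoculum,
                              BatchConfig(is_ratio=1.0, ca_ratio=0.5))
        assert state.S_Ca == pytest.approx(potential_lcfa(NS1, BatchConfig()))

    def test_total_initial_cod_is_substrate_plus_inoculum(self, inoculum):
        state = initial_state(NS1, inoculum, BatchConfig(is_ratio=0.4))
        assert state.S_p + state.X_total == pytest.approx(
            28.3 + 0.4 * 10 * 1.42)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            InoculumSpec(split=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            InoculumSpec(ts_g_l=10.0, vs_g_l=12.0)


class TestMethaneCurveAndSmp:
    def test_volume_is_cod_times_conversion(self, ns1_trajectory):
        curve = methane_curve(ns1_trajectory)
        np.testing.assert_allclose(curve.volume,
                                   ns1_trajectory.series("S_m") * 0.35)
        assert np.all(np.diff(curve.volume) >= 0.0)

    def test_smp_is_volume_per_loading(self):
        days = np.arange(21.0)
        curve = MethaneCurve(days=days, volume=np.linspace(0, 5.6, 21))
        assert smp(curve, 10.0) == pytest.approx(0.56)
        low = MethaneCurve(days=days, volume=np.linspace(0, 3.8, 21))
        assert smp(low, 10.0) == pytest.approx(0.38)
        zero = MethaneCurve(days=days, volume=np.zeros(21))
        assert smp(zero, 10.0) == 0.0
        with pytest.raises(ValueError):
            smp(curve, 0.0)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            MethaneCurve(days=np.array([1.0, 2.0]),
                         volume=np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            MethaneCurve(days=np.array([1.0, 1.0]),
                         volume=np.array([1.0, 2.0]))


class TestSweep:
    def test_single_cell_matches_direct_simulation(self, inoculum, params):
        table = sweep(NS1, inoculum, params, biomass_ratios=[1.0],
                      ca_ratios=[0.0], rtol=1e-8, atol=1e-10)
        assert len(table) == 1
        # same initial state built by hand: inoculum COD = potential LCFA
        lcfa = potential_lcfa(NS1, BatchConfig())
        is_ratio = lcfa / (10.0 * inoculum.cod_vs)
        traj = simulate_batch(NS1, inoculum, BatchConfig(is_ratio=is_ratio),
                              params, rtol=1e-8, atol=1e-10)
        direct = smp(methane_curve(traj), 10.0)
        assert table.smp.iloc[0] == pytest.approx(direct, rel=1e-6)

    def test_no_inoculum_row_produces_no_methane(self, inoculum, params):
        table = sweep(NS1, inoculum, params, biomass_ratios=[0.0],
                      ca_ratios=[0.0, 1.0, 2.0], rtol=1e-7, atol=1e-9)
        assert np.all(table.smp == 0.0)

    def test_surface_monotone_in_biomass_axis(self, inoculum, params):
        table = sweep(NS1, inoculum, params,
                      biomass_ratios=[0.0, 0.5, 1.0], ca_ratios=[0.0, 1.0],
                      rtol=1e-7, atol=1e-9)
        surface = table.pivot(index="biomass_ratio", columns="ca_ratio",
                              values="smp").values
        assert np.all(np.diff(surface, axis=0) >= -1e-9)

    def test_empty_grid_rejected(self, inoculum, params):
        with pytest.raises(ValueError):
            sweep(NS1, inoculum, params, biomass_ratios=[], ca_ratios=[1.0])
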