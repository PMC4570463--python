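"""ODE core: inhibition factors, right-hand side, integration, COD balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcfad import (
    ModelParameters,
    ModelState,
    Trajectory,
    cod_report,
    compute_inhibition,
    inhibition_factor,
    integrate,
    integrate_fixed_step,
    rhs,
)
from lcfad.model import STATE_NAMES, _augmented_rhs


class TestInhibitionFactor:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # no LCFA present: no inhibition, regardless of biomass/calcium
            (dict(K_ifa=5, a=0.5, b=0.5, X_total=7.3, S_Ca=2.1, S_fa=0.0), 1.0),
            # LCFA present but nothing to adsorb to except cells: full inhibition
            (dict(K_ifa=5, a=0.5, b=0.5, X_total=0.0, S_Ca=0.0, S_fa=2.0), 0.0),
            # hand arithmetic: R = (0.5*2)/9.9, K = 5R/(5R + 9.9)
            (dict(K_ifa=5, a=0.5, b=0.5, X_total=2.0, S_Ca=0.0, S_fa=9.9),
             0.0485390),
        ],
    )
    def test_reference_values(self, kwargs, expected):
        assert inhibition_factor(**kwargs) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("bad", ["K_ifa", "a", "b", "X_total", "S_Ca", "S_fa"])
    def test_negative_inputs_rejected(self, bad):
        kwargs = dict(K_ifa=5.0, a=0.5, b=0.5, X_total=1.0, S_Ca=1.0, S_fa=1.0)
        kwargs[bad] = -0.1
        with pytest.raises(ValueError):
            inhibition_factor(**kwargs)

    def test_zero_inhibition_constant_rejected(self):
        with pytest.raises(ValueError):
            inhibition_factor(0.0, 0.5, 0.5, 1.0, 1.0, 1.0)

    def test_bounds_and_monotonicity_on_random_states(self, rng):
        """On 10^4 random states: K in [0,1], increasing in biomass and
        calcium, decreasing in LCFA, and a doubled calcium equivalent never
        lowers the factor."""
        n = 10_000
        x = rng.uniform(0, 30, n)
        ca = rng.uniform(0, 25, n)
        fa = rng.uniform(1e-6, 15, n)
        k = inhibition_factor(5.0, 0.5, 0.5, x, ca, fa)
        assert np.all((k >= 0) & (k <= 1))
        eps = 1e-6
        assert np.all(inhibition_factor(5.0, 0.5, 0.5, x + eps, ca, fa) >= k)
        assert np.all(inhibition_factor(5.0, 0.5, 0.5, x, ca + eps, fa) >= k)
        assert np.all(inhibition_factor(5.0, 0.5, 0.5, x, ca, fa + eps) <= k)
        assert np.all(inhibition_factor(5.0, 0.5, 0.5, x, 2 * ca, fa) >= k)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        k_ifa=st.floats(1e-3, 1e3),
        x=st.floats(0, 1e3),
        ca=st.floats(0, 1e3),
        fa=st.floats(0, 1e3),
    )
    def test_factor_always_in_unit_interval(self, k_ifa, x, ca, fa):
        k = inhibition_factor(k_ifa, 0.5, 0.5, x, ca, fa)
        assert 0.0 <= k <= 1.0


class TestComputeInhibition:
    def test_no_lcfa_limit(self, params):
        state = ModelState(S_p=10, X_h=1, X_v=1, X_m=1)
        k = compute_inhibition(params, state)
        assert (k.K_h, k.K_v, k.K_m) == (1.0, 1.0, 1.0)

    def test_equal_constants_give_equal_factors(self, params):
        state = ModelState(S_fa=9.9, X_h=1, X_v=1, X_m=1)
        k = compute_inhibition(params, state)
        # R = 1.5/9.9, each factor 5R/(5R + 9.9)
        assert k.K_h == pytest.approx(0.0710833, abs=1e-6)
        assert k.K_h == k.K_v == k.K_m

    def test_factor_ordering_follows_constants(self, rng):
        """Larger inhibition constant means weaker inhibition (larger K)."""
        p = ModelParameters(Khfa=8.0, Kvfa=5.0, Kmfa=1.5)
        for _ in range(50):
            state = ModelState(
                S_fa=float(rng.uniform(0.1, 12)),
                X_h=float(rng.uniform(0, 10)),
                X_v=float(rng.uniform(0, 10)),
                X_m=float(rng.uniform(0, 10)),
                S_Ca=float(rng.uniform(0, 20)),
            )
            k = compute_inhibition(p, state)
            assert k.K_h >= k.K_v >= k.K_m


class TestRhs:
    def test_empty_reactor_is_at_rest(self, params):
        assert np.all(rhs(params, ModelState()) == 0.0)

    def test_substrate_without_biomass_is_inert(self, params):
        assert np.all(rhs(params, ModelState(S_p=28.3)) == 0.0)

    def test_hydrolysis_with_single_group(self, params):
        """Hand arithmetic: hydrolysis flux 10 * 28.3/(0.5*1 + 28.3) * 1."""
        dy = rhs(params, ModelState(S_p=28.3, X_h=1.0))
        hyd = 10.0 * 28.3 / 28.8
        expected = {
            "S_p": -hyd + 0.8,          # uptake + decay recycle of X_h
            "S_h": hyd,
            "S_fa": 0.35 * hyd,
            "X_h": 0.05 * hyd - 0.8,
        }
        for name, value in expected.items():
            assert dy[STATE_NAMES.index(name)] == pytest.approx(value, rel=1e-12)
        for name in ("S_v", "S_m", "X_v", "X_m", "S_Ca"):
            assert dy[STATE_NAMES.index(name)] == 0.0

    def test_invalid_states_rejected(self, params):
        state = np.zeros(len(STATE_NAMES))
        state[0] = -1.0
        with pytest.raises(ValueError):
            rhs(params, state)
        state[0] = np.nan
        with pytest.raises(ValueError):
            rhs(params, state)


class TestIntegrate:
    def test_zero_state_stays_zero(self, params):
        traj = integrate(params, ModelState(), t_end=5.0)
        assert np.all(traj.states == 0.0)
        assert cod_report(traj).max_relative_drift == 0.0

    def test_biomass_only_recycles_through_substrate(self, params):
        """Decaying biomass feeds S_p which is re-hydrolysed; the COD
        balance (sum minus yield-growth credit) stays closed."""
        traj = integrate(params, ModelState(X_h=2.0, X_v=1.0, X_m=1.0),
                         t_end=20.0)
        s_p = traj.series("S_p")
        assert s_p[1] > 0.0          # decay creates particulate substrate
        assert traj.series("S_m")[-1] > 0.0   # ...which ends up as methane
        assert cod_report(traj).max_relative_drift <= 1e-6

    def test_methane_nondecreasing_and_states_nonnegative(self, ns1_trajectory):
        assert np.all(np.diff(ns1_trajectory.series("S_m")) >= 0.0)
        assert np.all(ns1_trajectory.states >= 0.0)

    def test_report_step_does_not_change_solution(self, params,
                                                  ns1_reference_state):
        coarse = integrate(params, ns1_reference_state, t_end=10.0,
                           report_step=1.0)
        fine = integrate(params, ns1_reference_state, t_end=10.0,
                         report_step=0.25)
        np.testing.assert_allclose(fine.states[::4], coarse.states,
                                   rtol=1e-6, atol=1e-8)

    def test_matches_fixed_step_oracle_short_run(self, params,
                                                 ns1_reference_state):
        adaptive = integrate(params, ns1_reference_state, t_end=5.0)
        fixed = integrate_fixed_step(params, ns1_reference_state, t_end=5.0,
                                     dt=1e-3)
        scale = np.abs(fixed.states).max(axis=0) + 1e-12
        err = np.abs(adaptive.states - fixed.states) / scale
        assert err.max() <= 1e-4

    def test_invalid_arguments(self, params):
        with pytest.raises(ValueError):
            integrate(params, ModelState(), t_end=-1.0)
        with pytest.raises(ValueError):
            integrate(params, ModelState(), t_end=1.0, report_step=0.0)


class TestTrajectoryAndCodReport:
    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0]),
                       states=np.zeros((2, 9)),
                       inhibition=np.ones((2, 3)),
                       growth_credit=np.zeros(2))
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0]),
                       states=np.full((2, 9), -1.0),
                       inhibition=np.ones((2, 3)),
                       growth_credit=np.zeros(2))

    def test_to_frame_layout(self, ns1_trajectory):
        frame = ns1_trajectory.to_frame()
        assert list(frame.columns) == ["time_d", *STATE_NAMES,
                                       "K_h", "K_v", "K_m"]
        assert len(frame) == len(ns1_trajectory)

    def test_balance_closes_on_reference_run(self, ns1_trajectory):
        assert cod_report(ns1_trajectory).max_relative_drift <= 1e-6

    def test_broken_rhs_is_flagged(self, params):
        """Negative control: dropping the decay→S_p recycle opens the
        balance, and the report must show it."""
        traj = integrate(
            params, ModelState(X_h=2.0, X_v=1.0, X_m=1.0), t_end=10.0,
            _rhs_factory=lambda p: _augmented_rhs(p, recycle_decay=False),
        )
        assert cod_report(traj).max_relative_drift > 1e-3


class TestModelParameters:
    def test_rejects_invalid_values(self):
        with pytest.raises(ValueError):
            ModelParameters(km_p=-1.0)
        with pytest.raises(ValueError):
            ModelParameters(Y_m=1.5)
        with pytest.raises(ValueError):
            ModelParameters(f_fa=1.2)

    def test_from_dict_rejects_unknown_names(self):
        with pytest.raises(KeyError):
            ModelParameters.from_dict({"km_p": 10.0, "bogus": 1.0})

    def test_state_validation(self):
        with pytest.raises(ValueError):
            ModelState(S_p=-0.5)
        with pytest.raises(ValueError):
            ModelState.from_array(np.zeros(5))
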