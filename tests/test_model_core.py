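"""Unit and property tests for the deterministic population model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cscdyn import (
    DEFAULT_INIT,
    DomainError,
    ModelParams,
    State,
    Trajectory,
    division_probability,
    get_scenario,
    plasticity_rate,
    saturation_factor,
    simulate,
    vector_field,
)
from cscdyn.fixed_points import fixed_point_f2
from cscdyn.scenarios import scenario_names


def make_params(**kw):
    base = dict(d=0.2, q0=1.0, eta=5.0, beta=2.0, gamma=1.0, alpha_a=1.0, alpha_m=1.0)
    base.update(kw)
    return ModelParams(**base)


# ---------------------------------------------------------------------------
# Parameter / state validation
# ---------------------------------------------------------------------------

class TestValidation:
    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            make_params(d=0.0)

    def test_S0_bounded(self):
        with pytest.raises(ValueError, match="S0"):
            make_params(S0=1.5)

    def test_large_step_width_warns(self):
        with pytest.warns(UserWarning, match="step-function"):
            make_params(sq=0.8)

    @pytest.mark.parametrize(
        "state",
        [dict(S=-0.1, D=0.0, a=0.0, m=0.0), dict(S=0.6, D=0.6, a=0.0, m=0.0),
         dict(S=0.1, D=0.1, a=-1.0, m=0.0)],
    )
    def test_invalid_state_rejected(self, state):
        with pytest.raises(DomainError):
            State(**state)


# ---------------------------------------------------------------------------
# Auxiliary functions
# ---------------------------------------------------------------------------

class TestAuxiliaryFunctions:
    @pytest.mark.parametrize(
        "D,a,expected",
        [(0.0, 0.0, 0.0), (0.0, 1.0, 5.0 / 6.0), (1.0, 1.0, 5.0 / 12.0)],
    )
    def test_division_probability_values(self, D, a, expected):
        p = make_params(eta=5.0, psi=1.0)
        assert division_probability(D, a, p) == pytest.approx(expected, abs=1e-12)

    def test_division_probability_domain_error(self):
        with pytest.raises(DomainError):
            division_probability(-0.1, 0.5, make_params())

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        D=st.floats(0, 1), a=st.floats(0, 100),
        da=st.floats(1e-6, 10), dD=st.floats(1e-6, 1),
    )
    def test_division_probability_monotone_and_bounded(self, D, a, da, dD):
        p = make_params(eta=5.0, psi=1.0)
        v = division_probability(D, a, p)
        assert 0 <= v < 1
        assert division_probability(D, a + da, p) >= v
        if D + dD <= 1:
            assert division_probability(D + dD, a, p) <= v

    def test_plasticity_rate_half_height_at_threshold(self):
        p = make_params(q0=1.0)
        assert plasticity_rate(p.m0, p) == pytest.approx(0.5, abs=1e-15)

    def test_plasticity_rate_saturates(self):
        p = make_params(q0=1.0)
        assert plasticity_rate(p.m0 + 10 * p.sq, p) == pytest.approx(1.0, abs=1e-8)
        assert plasticity_rate(0.0, p) < 1e-20

    @pytest.mark.parametrize(
        "S,D,expected",
        [(0.5, 0.5, 0.0), (0.0, 0.0, math.tanh(10.0)), (0.5, 0.4, math.tanh(1.0))],
    )
    def test_saturation_factor_values(self, S, D, expected):
        assert saturation_factor(S, D, make_params()) == pytest.approx(expected, abs=1e-12)

    def test_saturation_factor_domain_error(self):
        with pytest.raises(DomainError):
            saturation_factor(0.6, 0.5, make_params())


# ---------------------------------------------------------------------------
# Vector field
# ---------------------------------------------------------------------------

class TestVectorField:
    def test_extinction_point_is_equilibrium(self):
        p = make_params(gamma=1.3, alpha_m=0.65)
        f = vector_field(State(0, 0, 0, p.gamma / p.alpha_m), p)
        assert np.all(f == 0.0)

    def test_closed_form_colony_near_equilibrium(self, fig1b_params):
        f2 = fixed_point_f2(fig1b_params, classify=False)
        res = vector_field(f2.location, fig1b_params)
        assert np.max(np.abs(res)) < 1e-6

    def test_stemless_state_pure_death(self):
        p = make_params(d=0.7)
        f = vector_field(State(0.0, 0.3, 0.0, 0.1), p)  # m << m0: q ~ 0
        assert f[1] == pytest.approx(-0.7 * 0.3, abs=1e-12)
        assert abs(f[0]) < 1e-12

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        S=st.floats(0, 0.9), Dfrac=st.floats(0, 1),
        a=st.floats(0, 50), m=st.floats(0, 5),
    )
    def test_mass_balance(self, S, Dfrac, a, m):
        """dS/dt + dD/dt equals net growth: one new cell per stem division
        minus DC death, independent of the division outcome split."""
        p = make_params()
        D = Dfrac * (1.0 - S)
        f = vector_field(State(S, D, a, m), p)
        expected = saturation_factor(S, D, p) * p.lambda_mitotic * S - p.d * D
        assert f[0] + f[1] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_fixed_point_initial_state_stays_put(self, fig1b_params):
        p = fig1b_params
        init = State(0, 0, 0, p.gamma / p.alpha_m)
        traj = simulate(p, init, 20.0)
        assert np.max(np.abs(traj.states - init.as_array())) < 1e-8

    def test_colony_regime_converges_to_closed_form(self, fig1b_params):
        sc = get_scenario("fig1b")
        traj = simulate(sc.model, sc.init, 20.0)
        f2 = fixed_point_f2(sc.model, classify=False).location.as_array()
        rel = np.abs(traj.states[-1] - f2) / np.maximum(np.abs(f2), 1.0)
        assert np.max(rel) < 0.01

    def test_overshoot_then_regression(self, fig5d_params):
        sc = get_scenario("fig5d")
        traj = simulate(sc.model, sc.init, sc.t_end)
        total = traj.S + traj.D
        assert total.max() > total[-1]
        assert not traj.has_event("divergence")

    def test_extinction_event_recorded(self):
        # plasticity never activates (gamma/alpha_m < m0), so DCs just die out
        p = make_params(d=1.2, gamma=0.3, alpha_m=1.0)
        traj = simulate(p, State(0.0, 0.1, 0.0, 0.3), 20.0)
        assert traj.has_event("extinction")
        assert traj.S[-1] + traj.D[-1] < 1e-6

    def test_divergence_event_halts_run(self):
        sc = get_scenario("fig6a")
        traj = simulate(sc.model, sc.init, sc.t_end)
        assert traj.has_event("divergence")
        assert traj.metadata["terminated_early"]
        assert traj.times[-1] < sc.t_end

    @pytest.mark.parametrize("name", scenario_names())
    def test_domain_conservation(self, name):
        """Cell fractions stay in the simplex on every fixture regime."""
        sc = get_scenario(name)
        traj = simulate(sc.model, sc.init, sc.t_end, dt_out=0.05)
        assert traj.S.min() >= -1e-9 and traj.D.min() >= -1e-9
        assert (traj.S + traj.D).max() <= 1 + 1e-9
        assert traj.a.min() >= -1e-9 and traj.m.min() >= -1e-9

    @pytest.mark.parametrize("name", ["fig1a", "fig1b", "fig5a", "fig7a"])
    def test_step_halving_consistency(self, name):
        sc = get_scenario(name)
        end_lo = simulate(sc.model, sc.init, sc.t_end, rtol=1e-6, atol=1e-9).states[-1]
        end_hi = simulate(sc.model, sc.init, sc.t_end, rtol=1e-9, atol=1e-12).states[-1]
        assert np.max(np.abs(end_lo - end_hi)) < 1e-4

    def test_trajectory_grid_and_frame(self):
        traj = simulate(make_params(), DEFAULT_INIT, 2.0, dt_out=0.1)
        assert np.all(np.diff(traj.times) > 0)
        df = traj.to_frame()
        assert list(df.columns) == ["t", "S", "D", "a", "m"]
        assert len(df) == traj.times.size

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            simulate(make_params(), DEFAULT_INIT, -1.0)

    def test_bad_trajectory_grid_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0, 1.0]), states=np.zeros((3, 4)))
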