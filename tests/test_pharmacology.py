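"""PK dosing model, PD action function and therapy adapters."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cscdyn import (
    ActionParams,
    DrugSchedule,
    TherapySpec,
    dose_rate_for_peak,
    drug_action,
    drug_level,
    effective_params,
    get_scenario,
    simulate,
    simulate_with_therapy,
)

REF = dict(chi_max=1.0, alpha_d=10.0, T=1.0, tau=0.08)


def ref_schedule(**kw):
    d = dict(REF)
    d.update(kw)
    return DrugSchedule(**d)


def integrate_pk_numerically(schedule, t_eval):
    """Independent oracle: direct ODE integration of the dosing equation,
    restarted at every switch so the discontinuity is respected."""
    zeta, ad = schedule.zeta_effective, schedule.alpha_d

    def dosing_at(t):
        if t < schedule.t_start:
            return False
        s = t - schedule.t_start
        n = math.floor(s / schedule.T)
        if schedule.n_periods is not None and n >= schedule.n_periods:
            return False
        return (s - n * schedule.T) < schedule.tau

    edges = np.unique(
        np.concatenate([schedule.phase_boundaries(t_eval[-1]), [0.0, t_eval[-1]]])
    )
    chi, out_t, out_v = 0.0, [0.0], [0.0]
    for t0, t1 in zip(edges[:-1], edges[1:]):
        rate = zeta if dosing_at((t0 + t1) / 2) else 0.0
        inner = [t for t in t_eval if t0 < t <= t1] + [t1]
        sol = solve_ivp(
            lambda t, y: [rate - ad * y[0]], (t0, t1), [chi],
            rtol=1e-12, atol=1e-14, t_eval=sorted(set(inner)),
        )
        chi = sol.y[0, -1]
        out_t += list(sol.t)
        out_v += list(sol.y[0])
    return np.array(out_t), np.array(out_v)


class TestDoseRate:
    def test_reference_value(self):
        z = dose_rate_for_peak(1.0, 10.0, 0.08)
        assert z == pytest.approx(10.0 / (1.0 - math.exp(-0.8)), rel=1e-12)
        assert z == pytest.approx(18.1597, abs=1e-4)

    def test_fast_clearance_limit(self):
        assert dose_rate_for_peak(2.0, 500.0, 1.0) == pytest.approx(1000.0, rel=1e-9)

    def test_round_trip_peak(self):
        sched = ref_schedule()
        assert drug_level(REF["tau"], sched) == pytest.approx(REF["chi_max"], abs=1e-9)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            dose_rate_for_peak(1.0, 10.0, 0.0)


class TestDrugLevel:
    def test_first_interval_closed_form(self):
        sched = ref_schedule()
        zeta, ad = sched.zeta_effective, sched.alpha_d
        t = np.linspace(0, REF["tau"], 20)
        expected = zeta * (1.0 - np.exp(-ad * t)) / ad
        assert drug_level(t, sched) == pytest.approx(expected, abs=1e-12)

    def test_peak_attained_at_end_of_dosing(self):
        sched = ref_schedule()
        t = np.linspace(0, 1.0, 20001)
        chi = drug_level(t, sched)
        assert chi.max() == pytest.approx(1.0, abs=1e-9)
        assert t[chi.argmax()] == pytest.approx(REF["tau"], abs=1e-3)

    def test_negligible_accumulation_across_period(self):
        sched = ref_schedule()
        ratio = drug_level(1.0, sched) / drug_level(REF["tau"], sched)
        assert ratio == pytest.approx(math.exp(-10.0 * 0.92), rel=1e-9)

    def test_matches_numerical_integration_over_ten_periods(self):
        sched = ref_schedule()
        t_eval = np.linspace(0, 10.0, 2001)
        t_num, chi_num = integrate_pk_numerically(sched, t_eval)
        assert drug_level(t_num, sched) == pytest.approx(chi_num, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_numerics_for_random_schedules(self, seed):
        rng = np.random.default_rng(seed)
        ad = rng.uniform(5, 30)
        T = rng.uniform(0.5, 2.0)
        tau = rng.uniform(0.02, 0.2) * T
        sched = DrugSchedule(alpha_d=ad, T=T, tau=tau, chi_max=rng.uniform(0.5, 3.0))
        t_eval = np.linspace(0, 5 * T, 1001)
        t_num, chi_num = integrate_pk_numerically(sched, t_eval)
        assert drug_level(t_num, sched) == pytest.approx(chi_num, abs=1e-8)

    def test_periodic_steady_state_geometric_buildup(self):
        with pytest.warns(UserWarning, match="accumulate"):
            sched = DrugSchedule(alpha_d=2.0, T=1.0, tau=0.5, chi_max=1.0)
        levels = np.array([drug_level(n * 1.0, sched) for n in range(1, 8)])
        diffs = np.diff(levels)
        assert np.all(diffs > 0)  # monotone build-up
        ratios = diffs[1:] / diffs[:-1]
        assert ratios == pytest.approx(math.exp(-2.0), rel=1e-9)

    def test_quiet_before_start_and_after_last_period(self):
        sched = ref_schedule(t_start=2.0, n_periods=3)
        assert drug_level(1.9, sched) == 0.0
        # after the last administration: pure exponential decay
        c5, c6 = drug_level(5.5, sched), drug_level(6.5, sched)
        assert c6 == pytest.approx(c5 * math.exp(-10.0), rel=1e-9)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            DrugSchedule(alpha_d=10.0, T=1.0, tau=1.5, chi_max=1.0)
        with pytest.raises(ValueError):
            DrugSchedule(alpha_d=10.0, T=1.0, tau=0.08, chi_max=1.0, zeta=5.0)


class TestDrugAction:
    ACT = ActionParams(omega0=1.0, chi0=0.2, s_chi=0.05)

    def test_half_maximum_at_midpoint(self):
        assert drug_action(0.2, self.ACT) == pytest.approx(0.5, abs=1e-15)

    def test_saturation_plateau(self):
        assert drug_action(50.0, self.ACT) == pytest.approx(1.0, abs=1e-12)

    def test_leakage_at_zero_level(self):
        assert drug_action(0.0, self.ACT) == pytest.approx(
            (math.tanh(-4.0) + 1.0) / 2.0, rel=1e-12
        )
        assert drug_action(0.0, self.ACT) == pytest.approx(3.3535e-4, rel=1e-3)

    def test_monotone(self):
        chi = np.linspace(0, 2, 200)
        omega = drug_action(chi, self.ACT)
        assert np.all(np.diff(omega) >= 0)  # plateaus are flat to precision
        mid = (chi > 0.1) & (chi < 0.3)
        assert np.all(np.diff(omega[mid]) > 0)


class TestEffectiveParams:
    def test_cytotoxic_peak_death_rate(self):
        sc = get_scenario("fig5a")
        t = np.linspace(0, 1, 4001)
        d_eff = np.array([effective_params(ti, sc.model, sc.therapy)["d"] for ti in t])
        assert d_eff.max() == pytest.approx(0.95 + 1.0, abs=1e-3)

    def test_no_dosing_leaves_base_parameters_up_to_leakage(self):
        sc = get_scenario("fig5a")
        import dataclasses

        late_start = dataclasses.replace(
            sc.therapy, schedule=ref_schedule(t_start=100.0)
        )
        eff = effective_params(5.0, sc.model, late_start)
        assert eff["d"] == pytest.approx(sc.model.d, abs=1.0 * 3.4e-4)
        assert eff["lambda_mitotic"] == sc.model.lambda_mitotic
        assert eff["q0"] == sc.model.q0

    def test_cytostatic_clamp_floors_at_zero(self, fig1b_params):
        th = TherapySpec(
            "cytostatic", ref_schedule(),
            ActionParams(omega0=5.0, chi0=0.2, s_chi=0.05),
        )
        lam = effective_params(0.05, fig1b_params, th)["lambda_mitotic"]
        assert lam >= 0.0

    def test_combined_carries_q_offset(self, fig1b_params):
        sc = get_scenario("fig8a")
        eff = effective_params(0.08, sc.model, sc.therapy)
        assert eff["q_offset"] > 0.9  # near Omega0 at peak level
        assert eff["d"] > sc.model.d

    def test_wrong_action_arity_rejected(self):
        act = ActionParams(1.0, 0.2, 0.05)
        with pytest.raises(ValueError):
            TherapySpec("differentiation_plus_cytotoxic", ref_schedule(), act)
        with pytest.raises(ValueError):
            TherapySpec("cytotoxic", ref_schedule(), (act, act))
        with pytest.raises(ValueError):
            TherapySpec("radiation", ref_schedule(), act)


class TestTherapySimulation:
    def test_null_therapy_matches_untreated(self):
        sc = get_scenario("fig1b")
        null = TherapySpec(
            "cytotoxic", ref_schedule(),
            ActionParams(omega0=1e-12, chi0=0.2, s_chi=0.05),
        )
        treated = simulate_with_therapy(sc.model, null, sc.init, 10.0)
        control = simulate(sc.model, sc.init, 10.0)
        common = np.intersect1d(np.round(treated.times, 9), np.round(control.times, 9))
        it = np.searchsorted(np.round(treated.times, 9), common)
        ic = np.searchsorted(np.round(control.times, 9), common)
        assert np.max(np.abs(treated.states[it] - control.states[ic])) < 1e-6

    def test_effective_rate_path_exported(self):
        sc = get_scenario("fig5a")
        traj = simulate_with_therapy(sc.model, sc.therapy, sc.init, 3.0)
        assert "chi" in traj.param_path and "d" in traj.param_path
        # later-period peaks exceed the first-dose peak by the tiny carry-over
        assert traj.param_path["chi"].max() == pytest.approx(1.0, abs=2e-4)
        df = traj.to_frame()
        assert "chi" in df.columns
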