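"""Solution and depot PK models: closed forms, ODE agreement, mass balance."""

import math

import numpy as np
import pytest
from scipy import stats

from leupkpd import params
from leupkpd.ode import integrate
from leupkpd.pk import (
    ConcSeries,
    DepotParams,
    Dose,
    ParameterError,
    SolutionPKParams,
    depot_release_profile,
    depot_system,
    simulate_depot,
    simulate_iv,
    simulate_sc_solution,
    solution_closed_form,
)


class TestSolutionModels:
    def test_iv_initial_concentration(self, iv_dose):
        series = simulate_iv(params.SOLUTION_PK_IV, iv_dose, [0.0, 1.0])
        assert series.values[0] == pytest.approx(iv_dose.amount / 192.95)

    def test_iv_half_life(self, iv_dose):
        p = SolutionPKParams(k_a=None, CL=1.386 * 100.0, V_d=100.0)  # k = 1.386
        series = simulate_iv(p, iv_dose, [0.0, 0.5])
        assert series.values[1] / series.values[0] == pytest.approx(0.5, rel=1e-3)

    def test_iv_two_hour_fraction_at_reported_k(self, iv_dose):
        """With the reported IV elimination constant, C(2h)/C0 = e^-2.84."""
        p = SolutionPKParams(k_a=None, CL=params.REPORTED_K_IV * 100.0, V_d=100.0)
        series = simulate_iv(p, iv_dose, [0.0, 2.0])
        assert series.values[1] / series.values[0] == pytest.approx(
            math.exp(-2.84), rel=1e-12
        )

    def test_bateman_zero_at_time_zero(self, sc_dose):
        series = solution_closed_form(params.SOLUTION_PK_SC, sc_dose, [0.0, 1.0])
        assert series.values[0] == 0.0

    def test_bateman_tmax_at_published_sc_parameters(self, sc_dose):
        """T_max = ln(k_a/k)/(k_a - k) ~ 0.1767 h for the SC solution set."""
        p = params.SOLUTION_PK_SC
        ka, k = p.k_a, p.k
        tmax = math.log(ka / k) / (ka - k)
        assert tmax == pytest.approx(0.1767, abs=2e-4)
        t = np.array([tmax - 0.01, tmax, tmax + 0.01])
        series = solution_closed_form(p, sc_dose, t)
        assert series.values[1] == max(series.values)

    def test_bateman_high_ka_limit_approaches_iv(self, sc_dose, iv_dose):
        fast = SolutionPKParams(k_a=5e3, CL=514.46, V_d=487.40)
        t = np.array([0.5, 1.0, 2.0])
        sc = solution_closed_form(fast, sc_dose, t)
        iv = simulate_iv(SolutionPKParams(k_a=None, CL=514.46, V_d=487.40),
                         iv_dose, t)
        assert np.allclose(sc.values, iv.values, rtol=2e-3)

    def test_ka_equals_k_falls_back_to_confluent_limit(self, sc_dose):
        p = SolutionPKParams(k_a=1.0, CL=100.0, V_d=100.0)
        series = solution_closed_form(p, sc_dose, [1.0])
        expected = sc_dose.amount * 1.0 * 1.0 * math.exp(-1.0) / 100.0
        assert series.values[0] == pytest.approx(expected, rel=1e-6)

    def test_rk4_matches_bateman_within_1e6(self, sc_dose, drug_times):
        """The ODE path reproduces the closed form to < 1e-6 relative."""
        ode = simulate_sc_solution(params.SOLUTION_PK_SC, sc_dose, drug_times)
        closed = solution_closed_form(params.SOLUTION_PK_SC, sc_dose, drug_times)
        rel = np.abs(ode.values - closed.values) / closed.values
        assert np.max(rel) < 1e-6

    def test_sc_mass_balance(self, sc_dose):
        """Everything absorbed is eventually eliminated: AUC = amount/CL."""
        p = params.SOLUTION_PK_SC
        t = np.linspace(0.0, 48.0, 2000)
        series = simulate_sc_solution(p, sc_dose, t)
        auc = np.trapezoid(series.values, t) + series.values[-1] / p.k
        assert auc == pytest.approx(sc_dose.amount / p.CL, rel=1e-3)

    def test_route_validation(self, iv_dose):
        with pytest.raises(ParameterError):
            solution_closed_form(params.SOLUTION_PK_SC, iv_dose, [1.0])


class TestDepotModel:
    def test_fraction_sum_closure_is_validated(self):
        DepotParams(N_R=0.18, D_R=0.28, E_R=0.54, k_d=0.08, k_t=0.0078,
                    t_lag_d=0.47, t_lag_e=3.61, ES_n=2)  # accepted
        with pytest.raises(ParameterError, match="sum to 1"):
            DepotParams(N_R=0.19, D_R=0.28, E_R=0.54, k_d=0.08, k_t=0.0078,
                        t_lag_d=0.47, t_lag_e=3.61, ES_n=2)

    def test_pure_ns_reduces_to_solution_model(self, depot_dose, sc_dose):
        depot = DepotParams(N_R=1.0, D_R=0.0, E_R=0.0, k_d=0.08, k_t=0.0078,
                            t_lag_d=0.47, t_lag_e=3.61, ES_n=2)
        t = np.array([0.25, 1.0, 4.0, 24.0])
        dep = simulate_depot(depot, params.SOLUTION_PK_SC, depot_dose, t)
        sol = simulate_sc_solution(params.SOLUTION_PK_SC, sc_dose, t)
        assert np.allclose(dep.values, sol.values, rtol=1e-9)

    def test_dose_is_conserved_at_time_zero(self, depot_dose):
        handle = depot_system(params.DEPOT_WISTAR, params.SOLUTION_PK_SC, depot_dose)
        traj = integrate(handle.system, handle.y0, [0.0])
        depot_states = traj[0, :4]  # NS, DS, ES_1, ES_2
        assert depot_states.sum() == pytest.approx(depot_dose.amount, rel=1e-12)

    def test_mass_balance_at_every_output_time(self, depot_dose):
        handle = depot_system(params.DEPOT_WISTAR, params.SOLUTION_PK_SC, depot_dose)
        t = np.array([0.0, 0.25, 1.0, 8.0, 24.0, 168.0, 336.0])
        traj = integrate(handle.system, handle.y0, t)
        totals = traj.sum(axis=1)
        assert np.allclose(totals, depot_dose.amount, rtol=1e-6)

    def test_states_stay_nonnegative(self, depot_dose):
        handle = depot_system(params.DEPOT_WISTAR, params.SOLUTION_PK_SC, depot_dose)
        traj = integrate(handle.system, handle.y0, np.linspace(0, 336, 100))
        assert np.min(traj) >= 0.0

    def test_erosive_chain_release_matches_gamma_oracle(self, depot_dose):
        """Cumulative erosive release follows the 2-stage Erlang CDF."""
        depot = params.DEPOT_WISTAR
        handle = depot_system(depot, params.SOLUTION_PK_SC, depot_dose)
        traj = integrate(handle.system, handle.y0, [0.0, 336.0], step=0.05)
        remaining = traj[1, 2] + traj[1, 3]  # ES_1 + ES_2
        released = depot.E_R - remaining / depot_dose.amount
        expected = depot.E_R * stats.gamma.cdf(
            336.0 - depot.t_lag_e, a=2, scale=1.0 / depot.k_t
        )
        assert expected == pytest.approx(0.54 * 0.736, rel=0.01)
        assert released == pytest.approx(expected, rel=1e-4)

    def test_release_profile_limits_and_sections(self):
        depot = params.DEPOT_WISTAR
        ka = params.SOLUTION_PK_SC.k_a
        t = np.array([1e-9, depot.t_lag_e, 1e7])
        profile = depot_release_profile(depot, t, k_a=ka)
        assert profile[0] == pytest.approx(0.0, abs=1e-6)
        assert profile[-1] == pytest.approx(1.0, abs=1e-9)
        # at the erosive lag instant only NS and DS have released anything
        te = depot.t_lag_e
        expected = depot.N_R * (1 - math.exp(-ka * te)) + depot.D_R * (
            1 - math.exp(-depot.k_d * (te - depot.t_lag_d))
        )
        assert profile[1] == pytest.approx(expected, rel=1e-12)

    def test_release_profile_monotone(self):
        t = np.linspace(0.001, 500.0, 400)
        profile = depot_release_profile(params.DEPOT_WISTAR, t, k_a=16.67)
        assert np.all(np.diff(profile) >= 0)

    def test_depot_auc_equals_dose_over_cl(self, depot_dose):
        """AUC_0-inf = released fraction x amount / CL (here fraction -> 1)."""
        p = params.SOLUTION_PK_SC
        # dense early grid: the non-encapsulated spike is over within hours
        t = np.concatenate(
            [np.linspace(0.0, 24.0, 2400, endpoint=False),
             np.linspace(24.0, 3000.0, 4000)]
        )
        series = simulate_depot(params.DEPOT_WISTAR, p, depot_dose, t, step=0.1)
        auc = np.trapezoid(series.values, t) + series.values[-1] / p.k
        released = depot_release_profile(params.DEPOT_WISTAR, [3000.0], p.k_a)[0]
        assert auc == pytest.approx(released * depot_dose.amount / p.CL, rel=5e-3)


class TestTypes:
    def test_dose_from_nominal_converts_units(self):
        dose = Dose.from_nominal(0.1, 0.3, "SC-depot")
        assert dose.amount == pytest.approx(0.1 * 0.3 * 1e6)

    def test_conc_series_rejects_negative_values(self):
        with pytest.raises(ParameterError):
            ConcSeries("leuprolide", [0.0, 1.0], [1.0, -0.1])

    def test_conc_series_rejects_unsorted_times(self):
        with pytest.raises(ParameterError):
            ConcSeries("leuprolide", [1.0, 0.0], [1.0, 1.0])

    def test_solution_params_require_positive(self):
        with pytest.raises(ParameterError):
            SolutionPKParams(k_a=16.67, CL=-1.0, V_d=487.4)
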