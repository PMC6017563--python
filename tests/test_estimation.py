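"""Fitting layer: noise-free recovery, model selection, diagnostics."""

import warnings

import numpy as np
import pytest

from leupkpd import params
from leupkpd.estimation import (
    diagnostics,
    fit_baseline_pd,
    fit_depot_pk,
    fit_pd,
    fit_solution_pk,
    select_transit_count,
)
from leupkpd.pd import simulate_baseline, simulate_pd
from leupkpd.pk import (
    ConcSeries,
    DepotParams,
    SolutionPKParams,
    depot_system,
    simulate_depot,
    simulate_iv,
    solution_closed_form,
)


class TestSolutionFit:
    def test_sc_recovery_from_perturbed_starts(self, sc_dose, drug_times):
        truth = params.SOLUTION_PK_SC
        data = solution_closed_form(truth, sc_dose, drug_times)
        init = {"k_a": truth.k_a * 2, "CL": truth.CL * 0.5, "V_d": truth.V_d * 2}
        fit = fit_solution_pk(data, "SC-solution", sc_dose, init=init,
                              n_starts=3, seed=1)
        assert fit.params["k_a"] == pytest.approx(truth.k_a, rel=5e-3)
        assert fit.params["CL"] == pytest.approx(truth.CL, rel=5e-3)
        assert fit.params["V_d"] == pytest.approx(truth.V_d, rel=5e-3)

    def test_iv_recovery_of_elimination_constant(self, iv_dose, drug_times):
        truth = params.SOLUTION_PK_IV
        data = simulate_iv(truth, iv_dose, drug_times[:8])
        fit = fit_solution_pk(data, "IV", iv_dose,
                              init={"CL": 100.0, "V_d": 400.0}, n_starts=3, seed=0)
        assert fit.extras["k"] == pytest.approx(truth.k, rel=5e-3)

    def test_perfect_init_gives_zero_objective(self, sc_dose, drug_times):
        truth = params.SOLUTION_PK_SC
        data = solution_closed_form(truth, sc_dose, drug_times)
        fit = fit_solution_pk(
            data, "SC-solution", sc_dose,
            init={"k_a": truth.k_a, "CL": truth.CL, "V_d": truth.V_d},
            n_starts=1, seed=0, simplex_maxfev=0,
        )
        assert fit.objective < 1e-12
        assert fit.objective <= 1e-12 or fit.convergence["success"]

    def test_final_objective_not_above_initial(self, sc_dose, drug_times):
        truth = params.SOLUTION_PK_SC
        data = solution_closed_form(truth, sc_dose, drug_times)
        init = {"k_a": 5.0, "CL": 300.0, "V_d": 300.0}
        init_pred = solution_closed_form(
            SolutionPKParams(**init), sc_dose, drug_times
        )
        init_obj = float(np.sum(((data.values - init_pred.values)
                                 / init_pred.values) ** 2))
        fit = fit_solution_pk(data, "SC-solution", sc_dose, init=init,
                              n_starts=1, seed=0)
        assert fit.objective <= init_obj


class TestDepotFit:
    def test_noise_free_recovery_of_kt(self, depot_dose, drug_times):
        truth = params.DEPOT_WISTAR
        data = simulate_depot(truth, params.SOLUTION_PK_SC, depot_dose,
                              drug_times, step=0.05)
        fit = fit_depot_pk(data, depot_dose, params.SOLUTION_PK_SC,
                           n_starts=1, seed=2, step=0.05, simplex_maxfev=100)
        assert fit.extras["k_t"] == pytest.approx(truth.k_t, rel=0.01)
        assert fit.extras["N_R"] == pytest.approx(truth.N_R, rel=0.02)

    def test_fractions_sum_to_one_by_construction(self, depot_dose, drug_times):
        truth = params.DEPOT_IAR_COP
        data = simulate_depot(truth, params.SOLUTION_PK_SC, depot_dose,
                              drug_times, step=0.05)
        fit = fit_depot_pk(data, depot_dose, params.SOLUTION_PK_SC,
                           n_starts=1, seed=0, step=0.05, simplex_maxfev=40)
        total = fit.extras["N_R"] + fit.extras["D_R"] + fit.extras["E_R"]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_pure_ns_data_drives_other_fractions_to_zero(self, depot_dose, drug_times):
        truth = DepotParams(N_R=1.0, D_R=0.0, E_R=0.0, k_d=0.08, k_t=0.0078,
                            t_lag_d=0.47, t_lag_e=3.61, ES_n=2)
        data = simulate_depot(truth, params.SOLUTION_PK_SC, depot_dose,
                              drug_times, step=0.05)
        fit = fit_depot_pk(data, depot_dose, params.SOLUTION_PK_SC,
                           n_starts=1, seed=0, step=0.05, simplex_maxfev=100)
        assert fit.extras["N_R"] > 0.99
        assert fit.extras["D_R"] + fit.extras["E_R"] < 0.01


class TestTransitSelection:
    def test_single_candidate_returned(self, depot_dose, drug_times):
        data = simulate_depot(params.DEPOT_WISTAR, params.SOLUTION_PK_SC,
                              depot_dose, drug_times, step=0.05)
        chosen, fits = select_transit_count(
            data, depot_dose, params.SOLUTION_PK_SC, candidates=[3],
            n_starts=1, seed=0, step=0.05, simplex_maxfev=30,
        )
        assert chosen == 3 and set(fits) == {3}

    def test_recovers_five_stage_chain(self, depot_dose, drug_times):
        truth = DepotParams(N_R=0.18, D_R=0.28, E_R=0.54, k_d=0.08, k_t=0.0078,
                            t_lag_d=0.47, t_lag_e=3.61, ES_n=5)
        data = simulate_depot(truth, params.SOLUTION_PK_SC, depot_dose,
                              drug_times, step=0.05)
        chosen, _ = select_transit_count(
            data, depot_dose, params.SOLUTION_PK_SC, candidates=[2, 5],
            n_starts=1, seed=1, step=0.05, simplex_maxfev=60,
        )
        assert chosen == 5


class TestBaselineFit:
    def test_recovers_turnover_ratio(self):
        truth = params.PD_DEPOT_WISTAR
        data = simulate_baseline(truth, np.array([0.0, 8.0, 24.0, 168.0, 336.0]))
        fit = fit_baseline_pd(data)
        assert fit.params["k_in"] / fit.params["k_out"] == pytest.approx(
            truth.k_in / truth.k_out, rel=5e-3
        )
        assert fit.convergence["identifiable"]

    def test_flat_data_flagged_unidentifiable(self):
        data = ConcSeries("testosterone", [0.0, 24.0, 336.0], [4.25, 4.25, 4.25])
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_baseline_pd(data)
        assert not fit.convergence["identifiable"]
        # the ratio is still pinned by the flat level
        assert fit.params["k_in"] / fit.params["k_out"] == pytest.approx(4.25, rel=1e-3)


class TestPDFit:
    def test_noise_free_recovery_of_effect_parameters(self, depot_dose, drug_times):
        handle = depot_system(params.DEPOT_WISTAR, params.SOLUTION_PK_SC, depot_dose)
        truth = params.PD_DEPOT_WISTAR
        t = np.concatenate(([0.0], drug_times))
        data = simulate_pd(truth, handle, t, step=0.05)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_pd(data, handle, truth, n_starts=2, seed=1, step=0.05,
                         simplex_maxfev=50)
        for name in ("E_max", "EC_50", "h"):
            assert fit.params[name] == pytest.approx(getattr(truth, name), rel=0.01)


class TestDiagnostics:
    def test_perfect_fit_zero_residuals(self, sc_dose, drug_times):
        truth = params.SOLUTION_PK_SC
        data = solution_closed_form(truth, sc_dose, drug_times)
        fit = fit_solution_pk(
            data, "SC-solution", sc_dose,
            init={"k_a": truth.k_a, "CL": truth.CL, "V_d": truth.V_d},
            n_starts=1, seed=0, simplex_maxfev=0,
        )
        assert np.allclose(fit.residuals, 0.0, atol=1e-6)

    def test_residuals_within_band_at_moderate_noise(self, sc_dose, drug_times):
        """10% proportional noise keeps weighted residuals inside +/-4.

        Restricted to the quantifiable window (solution leuprolide is
        far below any assay limit after the first day).
        """
        rng = np.random.default_rng(42)
        truth = params.SOLUTION_PK_SC
        t = drug_times[:5]  # 0.25-8 h
        clean = solution_closed_form(truth, sc_dose, t)
        noisy = ConcSeries(
            "leuprolide", t,
            np.maximum(clean.values * (1 + 0.1 * rng.normal(size=len(clean))), 0.0),
        )
        fit = fit_solution_pk(noisy, "SC-solution", sc_dose, n_starts=3, seed=0)
        table = diagnostics(fit)
        assert not table["outlier"].any()
        assert np.nanmax(np.abs(table["weighted_residual"])) < 4.0

    def test_doubled_observation_unit_weight(self, sc_dose, drug_times):
        truth = params.SOLUTION_PK_SC
        clean = solution_closed_form(truth, sc_dose, drug_times)
        doubled = ConcSeries("leuprolide", drug_times, clean.values * 2.0)
        fit = fit_solution_pk(
            doubled, "SC-solution", sc_dose,
            init={"k_a": truth.k_a, "CL": truth.CL, "V_d": truth.V_d},
            n_starts=1, seed=0, simplex_maxfev=0,
        )
        # under proportional weighting, obs = 2*pred gives residual 1 per point
        pred = fit.predictions.values
        manual = (doubled.values - pred) / pred
        assert np.allclose(fit.residuals, manual)
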