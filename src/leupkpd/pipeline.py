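"""The full analysis pipeline, in the study's order.

Stages: baseline turnover fit (vehicle groups) -> solution PK fit (IV and
SC) -> depot PK fit with the solution disposition fixed -> PD fit with the
baseline constants fixed -> NCA and AUEC tables -> residual diagnostics.
A stage failure halts the run naming the stage; results of earlier stages
are preserved in the returned bundle and on disk.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimation import (
    FitResult,
    diagnostics,
    fit_baseline_pd,
    fit_depot_pk,
    fit_pd,
    fit_solution_pk,
)
from .io import (
    InputError,
    PipelineConfig,
    config_hash,
    group_mean_series,
    read_conc_table,
    series_from_frame,
    write_conc_table,
)
from .nca import aeuc_decompose, nca_summary
from .pd import PDParams
from .pk import Dose, SolutionPKParams, depot_system, iv_system, sc_solution_system

__all__ = ["PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _arms(frame: pd.DataFrame) -> pd.DataFrame:
    return frame[
        ["group", "species", "route", "formulation"]
    ].drop_duplicates().reset_index(drop=True)


def _fit_frame(fit: FitResult) -> dict:
    out = {"objective": fit.objective, "AIC": fit.AIC, "n_obs": fit.n_obs}
    for name, value in fit.params.items():
        out[name] = value
        se = fit.stderr.get(name)
        out[f"{name}_se"] = se if se is not None else np.nan
    for name, value in fit.extras.items():
        if isinstance(value, (int, float)):
            out[name] = value
    return out


def run_full_pipeline(config: PipelineConfig, data: pd.DataFrame | None = None) -> dict:
    """Run every stage on a long-format dataset and write all outputs.

    ``data`` may be given directly (e.g. from the synthetic generator);
    otherwise ``config.data_path`` is read.  Returns a bundle with the
    fitted results, the NCA/AUEC tables and the diagnostics tables.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": config_hash(config), "seed": config.seed,
              "leupkpd_version": __version__}
    bundle: dict = {"config": config, "fits": {}, "tables": {}}

    if data is None:
        if config.data_path is None:
            raise PipelineError("input", "no data and no data_path configured")
        try:
            data = read_conc_table(config.data_path)
        except (InputError, OSError) as exc:
            raise PipelineError("input", str(exc)) from exc
    arms = _arms(data)

    def mean_series(mask_formulation, mask_route=None, species=None, analyte="leuprolide"):
        sel = arms[arms["formulation"] == mask_formulation]
        if mask_route is not None:
            sel = sel[sel["route"] == mask_route]
        if species is not None:
            sel = sel[sel["species"] == species]
        if sel.empty:
            return None, None
        label = str(sel["group"].iloc[0])
        return group_mean_series(data, label, analyte), label

    # ---- stage 1: baseline turnover ------------------------------------
    baselines: dict[str, FitResult] = {}
    try:
        for species in arms["species"].unique():
            series, label = mean_series("vehicle", species=species,
                                        analyte="testosterone")
            if series is None:
                continue
            baselines[species] = fit_baseline_pd(series, weighting=config.weighting)
            baselines[species].extras["group"] = label
        if not baselines:
            raise InputError("no vehicle group found for the baseline stage")
    except (InputError, RuntimeError) as exc:
        raise PipelineError("baseline", str(exc)) from exc
    bundle["fits"]["baseline"] = baselines

    # ---- stage 2: solution PK ------------------------------------------
    try:
        solution_fits: dict[str, FitResult] = {}
        iv_series, _ = mean_series("solution", "IV")
        if iv_series is not None:
            dose = Dose.from_nominal(config.dose_mg_per_kg, config.body_weight_kg, "IV")
            solution_fits["IV"] = fit_solution_pk(
                iv_series, "IV", dose, weighting=config.weighting,
                n_starts=config.n_starts, seed=config.seed,
                simplex_maxfev=config.simplex_maxfev,
            )
        sc_series, _ = mean_series("solution", "SC")
        if sc_series is not None:
            dose = Dose.from_nominal(
                config.dose_mg_per_kg, config.body_weight_kg, "SC-solution"
            )
            solution_fits["SC"] = fit_solution_pk(
                sc_series, "SC-solution", dose, weighting=config.weighting,
                n_starts=config.n_starts, seed=config.seed,
                simplex_maxfev=config.simplex_maxfev,
            )
        if "SC" not in solution_fits:
            raise InputError("no SC solution group; depot disposition undefined")
    except (InputError, RuntimeError) as exc:
        raise PipelineError("solution-pk", str(exc)) from exc
    bundle["fits"]["solution"] = solution_fits
    sc_params = SolutionPKParams(
        k_a=solution_fits["SC"].params["k_a"],
        CL=solution_fits["SC"].params["CL"],
        V_d=solution_fits["SC"].params["V_d"],
    )

    # ---- stage 3: depot PK ---------------------------------------------
    depot_fits: dict[str, FitResult] = {}
    try:
        depot_arms = arms[arms["formulation"] == "depot"]
        dose = Dose.from_nominal(config.dose_mg_per_kg, config.body_weight_kg, "SC-depot")
        for _, arm in depot_arms.iterrows():
            label = str(arm["group"])
            series = group_mean_series(data, label, "leuprolide")
            depot_fits[label] = fit_depot_pk(
                series, dose, sc_params, weighting=config.weighting,
                n_starts=config.n_starts, seed=config.seed,
                step=config.solver_step, simplex_maxfev=config.simplex_maxfev,
            )
    except (InputError, RuntimeError) as exc:
        raise PipelineError("depot-pk", str(exc)) from exc
    bundle["fits"]["depot"] = depot_fits

    # ---- stage 4: PD ----------------------------------------------------
    pd_fits: dict[str, FitResult] = {}
    try:
        drug_arms = arms[arms["formulation"].isin(["solution", "depot"])]
        for _, arm in drug_arms.iterrows():
            label = str(arm["group"])
            species = arm["species"]
            if species not in baselines:
                # no vehicle arm of this species; use the one available
                species = next(iter(baselines))
            base = baselines[species]
            base_pd = PDParams(
                k_in=base.params["k_in"], k_out=base.params["k_out"],
                R0=base.extras["R0"],
                k_f_on=0.2, k_f_off=0.05, E_max=300.0, EC_50=3.0, h=2.0,
            )
            series = group_mean_series(data, label, "testosterone")
            if arm["formulation"] == "solution" and arm["route"] == "IV":
                dose = Dose.from_nominal(
                    config.dose_mg_per_kg, config.body_weight_kg, "IV"
                )
                iv_fit = solution_fits.get("IV", solution_fits["SC"])
                pk_pars = SolutionPKParams(
                    k_a=None, CL=iv_fit.params["CL"], V_d=iv_fit.params["V_d"]
                )
                handle = iv_system(pk_pars, dose)
            elif arm["formulation"] == "solution":
                dose = Dose.from_nominal(
                    config.dose_mg_per_kg, config.body_weight_kg, "SC-solution"
                )
                handle = sc_solution_system(sc_params, dose)
            else:
                dose = Dose.from_nominal(
                    config.dose_mg_per_kg, config.body_weight_kg, "SC-depot"
                )
                handle = depot_system(
                    depot_fits[label].extras["depot_params"], sc_params, dose
                )
            pd_fits[label] = fit_pd(
                series, handle, base_pd, weighting=config.weighting,
                n_starts=config.n_starts, seed=config.seed,
                step=config.solver_step, feedback_form=config.feedback_form,
                simplex_maxfev=config.simplex_maxfev,
            )
    except (InputError, RuntimeError) as exc:
        raise PipelineError("pd", str(exc)) from exc
    bundle["fits"]["pd"] = pd_fits

    # ---- stage 5: NCA / AUEC -------------------------------------------
    try:
        nca_rows = []
        iv_ref_auc = None
        drug_frame = data[data["analyte"] == "leuprolide"]
        for subject in drug_frame["subject_id"].unique():
            row0 = data[data["subject_id"] == subject].iloc[0]
            route = {
                ("IV", "solution"): "IV",
                ("SC", "solution"): "SC-solution",
                ("SC", "depot"): "SC-depot",
            }[(row0["route"], row0["formulation"])]
            dose = Dose.from_nominal(
                config.dose_mg_per_kg, config.body_weight_kg, route
            )
            series = series_from_frame(data, subject, "leuprolide")
            try:
                res = nca_summary(series, dose, terminal_points=config.terminal_k_points)
            except Exception:
                continue  # depot tails may not be log-linear per subject
            nca_rows.append(
                {"subject_id": subject, "group": row0["group"], "route": route,
                 **res.as_dict()}
            )
        nca_table = pd.DataFrame(nca_rows)
        if not nca_table.empty:
            iv = nca_table[nca_table["route"] == "IV"]
            if not iv.empty:
                iv_ref_auc = float(iv["AUC_0_inf"].mean())
                nca_table["F"] = 100.0 * nca_table["AUC_0_inf"] / iv_ref_auc

        auec_rows = []
        testo = data[data["analyte"] == "testosterone"]
        for subject in testo["subject_id"].unique():
            sub = testo[testo["subject_id"] == subject].sort_values("time_h")
            row0 = sub.iloc[0]
            if config.auec_baseline_mode == "subject":
                pre = sub[sub["time_h"] == 0.0]
                if pre.empty:
                    continue
                baseline = float(pre["conc_ng_ml"].iloc[0])
            else:
                species = row0["species"]
                base = baselines.get(species)
                baseline = base.extras["R0"] if base else float(
                    sub["conc_ng_ml"].iloc[0]
                )
            series = series_from_frame(data, subject, "testosterone", drop_bql=False)
            res = aeuc_decompose(series, baseline)
            auec_rows.append(
                {"subject_id": subject, "group": row0["group"],
                 "formulation": row0["formulation"], **res.as_dict()}
            )
        auec_table = pd.DataFrame(auec_rows)
    except (InputError, RuntimeError) as exc:
        raise PipelineError("nca-auec", str(exc)) from exc
    bundle["tables"]["nca"] = nca_table
    bundle["tables"]["auec"] = auec_table

    # ---- stage 6: diagnostics + outputs --------------------------------
    try:
        diag_frames = []
        for family, fits in bundle["fits"].items():
            for label, fit in fits.items():
                frame = diagnostics(fit)
                frame.insert(0, "fit", f"{family}:{label}")
                diag_frames.append(frame)
        diag_table = pd.concat(diag_frames, ignore_index=True)
        bundle["tables"]["diagnostics"] = diag_table

        fit_summary = pd.DataFrame(
            {
                f"{family}:{label}": _fit_frame(fit)
                for family, fits in bundle["fits"].items()
                for label, fit in fits.items()
            }
        ).T
        bundle["tables"]["fit_summary"] = fit_summary

        write_conc_table(nca_table, out_dir / "nca.csv", header)
        write_conc_table(auec_table, out_dir / "auec.csv", header)
        write_conc_table(diag_table, out_dir / "diagnostics.csv", header)
        write_conc_table(
            fit_summary.reset_index(names="fit"), out_dir / "fit_summary.csv", header
        )
        manifest = {
            **header,
            "config": asdict(config),
            "stages": sorted(bundle["fits"]),
            "iv_reference_auc": iv_ref_auc,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    except (OSError, ValueError) as exc:
        raise PipelineError("outputs", str(exc)) from exc
    return bundle
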