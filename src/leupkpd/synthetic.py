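"""Synthetic six-group rat study generator.

No animal data were deposited with the study this package models, so every
pipeline stage is exercised against simulated data that emulate the in
vivo design: six groups of five rats (IV solution, vehicle, SC solution
and SC depot in normal Wistar rats; vehicle and SC depot in Iar:COP
prostate-carcinoma rats), dosed at 0.1 mg/kg leuprolide, sampled at 0.25,
1, 2, 4, 8 h and 1-7, 11, 14 days (vehicle groups: 8 h, 1, 7, 14 days),
plus a pre-dose sample.

Variability model:

* inter-individual: each mean parameter is multiplied by an independent
  mean-1 lognormal deviate with coefficient of variation ``iiv_cv``
  (release fractions are renormalised back onto the simplex);
* residual: proportional error on both analytes, with an extra additive
  floor for testosterone (immunoassay noise near baseline);
* quantification limits: testosterone below the assay LLOQ is flagged
  BQL; values above the ULOQ are flagged as diluted but kept numeric.

Defaults are chosen so the simulated between-animal scatter is of the
same order as the reported SE/mean ratios of the study's parameter
tables.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import params as published
from .ode import DEFAULT_STEP
from .pd import PDParams, simulate_baseline, simulate_pd
from .pk import (
    DepotParams,
    Dose,
    ParameterError,
    SolutionPKParams,
    depot_system,
    iv_system,
    sc_solution_system,
    simulate_iv,
    solution_closed_form,
    simulate_depot,
)

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "NoiseModel",
    "GroupParams",
    "draw_individual_params",
    "generate_study",
    "fixture_suite",
    "default_parameter_sets",
    "DRUG_SAMPLING_H",
    "VEHICLE_SAMPLING_H",
]

#: Sampling schedule of the drug-treated groups (hours): 0.25-8 h then
#: days 1-7, 11 and 14.
DRUG_SAMPLING_H = (
    0.25, 1.0, 2.0, 4.0, 8.0,
    24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 264.0, 336.0,
)

#: Sampling schedule of the vehicle groups (hours): 8 h, days 1, 7 and 14.
VEHICLE_SAMPLING_H = (8.0, 24.0, 168.0, 336.0)


@dataclass(frozen=True)
class GroupSpec:
    """One study arm."""

    label: str
    species: str  # Wistar | Iar:COP
    route: str  # IV | SC
    formulation: str  # vehicle | solution | depot
    dose_mg_per_kg: float | None
    sampling_times_h: tuple = DRUG_SAMPLING_H


@dataclass(frozen=True)
class StudyDesign:
    """The six-group in vivo design (defaults reproduce it exactly)."""

    groups: tuple[GroupSpec, ...]
    n_per_group: int = 5
    body_weight_kg: float = published.DEFAULT_BODY_WEIGHT_KG

    @classmethod
    def default_rat_study(cls, n_per_group: int = 5) -> "StudyDesign":
        groups = (
            GroupSpec("1", "Wistar", "IV", "solution", 0.1, DRUG_SAMPLING_H),
            GroupSpec("2", "Wistar", "SC", "vehicle", None, VEHICLE_SAMPLING_H),
            GroupSpec("3", "Wistar", "SC", "solution", 0.1, DRUG_SAMPLING_H),
            GroupSpec("4", "Wistar", "SC", "depot", 0.1, DRUG_SAMPLING_H),
            GroupSpec("5", "Iar:COP", "SC", "vehicle", None, VEHICLE_SAMPLING_H),
            GroupSpec("6", "Iar:COP", "SC", "depot", 0.1, DRUG_SAMPLING_H),
        )
        return cls(groups=groups, n_per_group=n_per_group)


@dataclass(frozen=True)
class NoiseModel:
    """Inter-individual and residual variability settings."""

    iiv_cv: float = 0.25
    residual_cv_leuprolide: float = 0.10
    residual_cv_testosterone: float = 0.15
    testosterone_additive_sd: float = 0.1
    lloq_testosterone: float = 0.041
    uloq_testosterone: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "iiv_cv",
            "residual_cv_leuprolide",
            "residual_cv_testosterone",
            "testosterone_additive_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (self.lloq_testosterone < self.uloq_testosterone):
            raise ParameterError("LLOQ must be below ULOQ")

    def zero_noise(self) -> "NoiseModel":
        return replace(
            self,
            iiv_cv=0.0,
            residual_cv_leuprolide=0.0,
            residual_cv_testosterone=0.0,
            testosterone_additive_sd=0.0,
        )


@dataclass(frozen=True)
class GroupParams:
    """Mean parameter sets driving one arm's simulation."""

    pk: SolutionPKParams | None = None
    depot: DepotParams | None = None
    pd: PDParams | None = None


def default_parameter_sets() -> dict[str, GroupParams]:
    """The published mean parameter sets, keyed by group label."""
    return {
        "1": GroupParams(pk=published.SOLUTION_PK_IV, pd=published.PD_IV_WISTAR),
        "2": GroupParams(pd=published.PD_DEPOT_WISTAR),
        "3": GroupParams(pk=published.SOLUTION_PK_SC, pd=published.PD_SC_WISTAR),
        "4": GroupParams(
            pk=published.SOLUTION_PK_SC,
            depot=published.DEPOT_WISTAR,
            pd=published.PD_DEPOT_WISTAR,
        ),
        "5": GroupParams(pd=published.PD_DEPOT_IAR_COP),
        "6": GroupParams(
            pk=published.SOLUTION_PK_SC,
            depot=published.DEPOT_IAR_COP,
            pd=published.PD_DEPOT_IAR_COP,
        ),
    }


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return np.exp(rng.normal(-0.5 * sigma2, sigma, size=n))


def _perturb_dataclass(obj, rng: np.random.Generator, cv: float):
    """Multiply every positive float field by an independent lognormal deviate."""
    updates = {}
    for f in dc_fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, bool) or not isinstance(v, (int, float)) or v is None:
            continue
        if f.name == "ES_n":  # structural integer, not a biological parameter
            continue
        if v <= 0:
            continue
        updates[f.name] = float(v) * float(_lognormal_factors(rng, cv, 1)[0])
    if isinstance(obj, DepotParams):
        # renormalise the perturbed fractions back onto the simplex
        nr = updates.get("N_R", obj.N_R)
        dr = updates.get("D_R", obj.D_R)
        er = updates.get("E_R", obj.E_R)
        total = nr + dr + er
        updates["N_R"], updates["D_R"], updates["E_R"] = (
            nr / total, dr / total, er / total
        )
    return replace(obj, **updates)


def draw_individual_params(mean_params, noise: NoiseModel, n: int, rng=None) -> list:
    """Draw ``n`` individual parameter sets around the means.

    Each positive parameter gets an independent mean-1 lognormal multiplier
    with CV ``noise.iiv_cv``; depot release fractions are renormalised to
    the simplex afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return [_perturb_dataclass(mean_params, rng, noise.iiv_cv) for _ in range(n)]


def _simulate_subject(
    group: GroupSpec,
    pars: GroupParams,
    dose: Dose | None,
    times: np.ndarray,
    step: float,
    analytes: tuple,
) -> dict[str, np.ndarray]:
    """Noise-free model curves for one subject, per requested analyte."""
    out: dict[str, np.ndarray] = {}
    drug_handle = None
    if group.formulation == "vehicle":
        if "testosterone" in analytes:
            out["testosterone"] = simulate_baseline(pars.pd, times).values
        return out
    if group.formulation == "solution" and group.route == "IV":
        leu = simulate_iv(pars.pk, dose, times)
        drug_handle = iv_system(pars.pk, dose)
    elif group.formulation == "solution":
        leu = solution_closed_form(pars.pk, dose, times)
        drug_handle = sc_solution_system(pars.pk, dose)
    elif group.formulation == "depot":
        leu = simulate_depot(pars.depot, pars.pk, dose, times, step=step)
        drug_handle = depot_system(pars.depot, pars.pk, dose)
    else:
        raise ParameterError(f"unknown formulation {group.formulation!r}")
    if "leuprolide" in analytes:
        out["leuprolide"] = leu.values
    if "testosterone" in analytes:
        out["testosterone"] = simulate_pd(pars.pd, drug_handle, times, step=step).values
    return out


def generate_study(
    design: StudyDesign,
    params_by_group: Mapping[str, GroupParams] | None = None,
    noise: NoiseModel | None = None,
    step: float = DEFAULT_STEP,
    analytes: tuple = ("leuprolide", "testosterone"),
) -> pd.DataFrame:
    """Simulate the whole study as a long-format table.

    Columns: subject_id, group, species, route, formulation, analyte,
    time_h, conc_ng_ml, bql_flag.  Leuprolide is simulated with the
    route-appropriate PK model, testosterone with the linked PK-PD model
    (the drug-free turnover model for vehicle arms).  A pre-dose (t = 0)
    testosterone sample is always recorded.
    """
    if params_by_group is None:
        params_by_group = default_parameter_sets()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(noise.seed)
    rows = []
    for group in design.groups:
        if group.label not in params_by_group:
            raise ParameterError(
                f"no parameter set configured for group {group.label!r}"
            )
        means = params_by_group[group.label]
        if group.formulation != "vehicle" and (
            means.pk is None
            or (group.formulation == "depot" and means.depot is None)
        ):
            raise ParameterError(
                f"group {group.label!r} ({group.formulation}) needs PK parameters"
            )
        if means.pd is None:
            raise ParameterError(f"group {group.label!r} needs PD parameters")
        times = np.concatenate(([0.0], np.asarray(group.sampling_times_h, float)))
        for subj in range(1, design.n_per_group + 1):
            subject_id = f"G{group.label}-{subj:02d}"
            pars = GroupParams(
                pk=(
                    _perturb_dataclass(means.pk, rng, noise.iiv_cv)
                    if means.pk is not None
                    else None
                ),
                depot=(
                    _perturb_dataclass(means.depot, rng, noise.iiv_cv)
                    if means.depot is not None
                    else None
                ),
                pd=_perturb_dataclass(means.pd, rng, noise.iiv_cv),
            )
            dose = None
            if group.dose_mg_per_kg is not None:
                route = {
                    ("IV", "solution"): "IV",
                    ("SC", "solution"): "SC-solution",
                    ("SC", "depot"): "SC-depot",
                }[(group.route, group.formulation)]
                dose = Dose.from_nominal(
                    group.dose_mg_per_kg, design.body_weight_kg, route
                )
            curves = _simulate_subject(group, pars, dose, times, step, analytes)
            for analyte, values in curves.items():
                if analyte == "leuprolide":
                    eps = rng.normal(0.0, 1.0, size=values.size)
                    noisy = values * (1.0 + noise.residual_cv_leuprolide * eps)
                else:
                    eps = rng.normal(0.0, 1.0, size=values.size)
                    add = rng.normal(
                        0.0, 1.0, size=values.size
                    ) * noise.testosterone_additive_sd
                    noisy = values * (1.0 + noise.residual_cv_testosterone * eps) + add
                noisy = np.maximum(noisy, 0.0)
                for t, c in zip(times, noisy):
                    if analyte == "leuprolide" and (t == 0.0 or dose is None):
                        continue  # no pre-dose drug sample
                    flag = ""
                    if analyte == "testosterone":
                        if c < noise.lloq_testosterone:
                            flag = "BQL"
                        elif c > noise.uloq_testosterone:
                            flag = "diluted"
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "group": group.label,
                            "species": group.species,
                            "route": group.route,
                            "formulation": group.formulation,
                            "analyte": analyte,
                            "time_h": float(t),
                            "conc_ng_ml": float(c),
                            "bql_flag": flag,
                        }
                    )
    return pd.DataFrame(rows)


def fixture_suite(
    seed: int = 0, step: float = DEFAULT_STEP, out_dir=None
) -> dict[str, pd.DataFrame]:
    """Small deterministic dataset bundle for tests and worked examples.

    ``means``: noise-free per-group mean curves (one pseudo-subject per
    group); ``noisy``: one full noisy study; ``flat_baseline``: a
    degenerate vehicle set at exactly the baseline (identifiability edge
    case).  Identical seeds give identical frames; with ``out_dir`` the
    frames are also written as seed-stamped CSV files (byte-identical
    across runs with the same seed).
    """
    design = StudyDesign.default_rat_study()
    noise = NoiseModel(seed=seed)
    means = generate_study(
        replace(design, n_per_group=1),
        noise=noise.zero_noise(),
        step=step,
    )
    noisy = generate_study(design, noise=noise, step=step)
    flat_design = StudyDesign(
        groups=(GroupSpec("2", "Wistar", "SC", "vehicle", None, VEHICLE_SAMPLING_H),),
        n_per_group=3,
    )
    flat_pd = replace(
        published.PD_DEPOT_WISTAR, k_in=0.16 * 4.353, k_out=0.16, R0=4.353
    )
    flat = generate_study(
        flat_design,
        params_by_group={"2": GroupParams(pd=flat_pd)},
        noise=noise.zero_noise(),
        step=step,
    )
    bundle = {"means": means, "noisy": noisy, "flat_baseline": flat}
    if out_dir is not None:
        from .io import write_conc_table

        for name, frame in bundle.items():
            write_conc_table(frame, Path(out_dir) / f"{name}.csv", {"seed": seed})
    return bundle
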