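"""Published mean parameter sets from the six-group rat study.

These are the study's reported estimates (mean of n = 5 per-animal fits)
for leuprolide disposition after solution dosing, the sustained-release
depot release model, and the testosterone feedback turnover model, in
normal Wistar rats and in Iar:COP (Dunning prostate-carcinoma) rats.
They drive the synthetic-data generator and the worked examples; the
underlying animal data were never deposited.

Group numbering follows the in vivo design: 1 = IV solution (Wistar),
2 = vehicle (Wistar), 3 = SC solution (Wistar), 4 = SC depot (Wistar),
5 = vehicle (Iar:COP), 6 = SC depot (Iar:COP).
"""

from __future__ import annotations

from .pk import DepotParams, SolutionPKParams
from .pd import PDParams

__all__ = [
    "SOLUTION_PK_IV",
    "SOLUTION_PK_SC",
    "DEPOT_WISTAR",
    "DEPOT_IAR_COP",
    "PD_IV_WISTAR",
    "PD_SC_WISTAR",
    "PD_DEPOT_WISTAR",
    "PD_DEPOT_IAR_COP",
    "REPORTED_AUC_INF",
    "REPORTED_K_IV",
    "BASELINE_TESTOSTERONE",
    "NOMINAL_DOSE_MG_PER_KG",
    "DEFAULT_BODY_WEIGHT_KG",
    "pd_params_for_group",
]

#: One-compartment disposition after IV solution (Group 1).  No absorption
#: phase, hence no k_a.
SOLUTION_PK_IV = SolutionPKParams(k_a=None, CL=248.61, V_d=192.95)

#: One-compartment first-order absorption after SC solution (Group 3).
#: CL and V_d are apparent (dose/F convention): SC CL ~ IV CL / 0.506.
SOLUTION_PK_SC = SolutionPKParams(k_a=16.67, CL=514.46, V_d=487.40)

#: Three-section depot release, normal Wistar rats (Group 4).
DEPOT_WISTAR = DepotParams(
    N_R=0.18, D_R=0.28, E_R=0.54,
    k_d=0.08, k_t=0.0078,
    t_lag_d=0.47, t_lag_e=3.61,
    ES_n=2,
)

#: Three-section depot release, Iar:COP prostate-cancer rats (Group 6).
DEPOT_IAR_COP = DepotParams(
    N_R=0.08, D_R=0.43, E_R=0.49,
    k_d=0.08, k_t=0.0193,
    t_lag_d=0.35, t_lag_e=2.58,
    ES_n=2,
)

_WISTAR_TURNOVER = dict(k_in=0.68, k_out=0.16, R0=4.353)
_IAR_COP_TURNOVER = dict(k_in=0.35, k_out=0.06, R0=4.094)

#: Feedback turnover PD, IV solution group (Group 1).
PD_IV_WISTAR = PDParams(
    **_WISTAR_TURNOVER,
    k_f_on=0.29, k_f_off=0.059, E_max=303.77, EC_50=3.48, h=2.00,
)

#: Feedback turnover PD, SC solution group (Group 3).
PD_SC_WISTAR = PDParams(
    **_WISTAR_TURNOVER,
    k_f_on=0.14, k_f_off=0.02, E_max=183.50, EC_50=6.17, h=2.02,
)

#: Feedback turnover PD, SC depot group, normal Wistar (Group 4).
PD_DEPOT_WISTAR = PDParams(
    **_WISTAR_TURNOVER,
    k_f_on=0.40, k_f_off=0.04, E_max=380.00, EC_50=1.80, h=2.00,
)

#: Feedback turnover PD, SC depot group, Iar:COP (Group 6).
PD_DEPOT_IAR_COP = PDParams(
    **_IAR_COP_TURNOVER,
    k_f_on=0.083, k_f_off=0.45, E_max=634.50, EC_50=3.34, h=3.18,
)

#: Reported mean AUC_0-inf (h*ng/mL) from the non-compartmental analysis of
#: the solution groups; the IV value is the reference for bioavailability.
REPORTED_AUC_INF = {"IV": 105.50, "SC": 53.33}

#: Reported NCA elimination rate constant after IV solution (h^-1).
REPORTED_K_IV = 1.42

#: Mean basal plasma testosterone (ng/mL) in the vehicle groups.
BASELINE_TESTOSTERONE = {"Wistar": 4.35, "Iar:COP": 4.09}

#: Leuprolide dose in every drug group (mg base per kg body weight).
NOMINAL_DOSE_MG_PER_KG = 0.1

#: Rat body weight is unreported; a 0.3 kg adult male rat is assumed.
DEFAULT_BODY_WEIGHT_KG = 0.3


def pd_params_for_group(species: str, route: str, formulation: str) -> PDParams:
    """Return the published PD set for a study arm.

    Vehicle arms get the species' turnover constants with the drug-effect
    parameters of the corresponding depot arm (irrelevant at zero drug).
    """
    key = (species, route, formulation)
    table = {
        ("Wistar", "IV", "solution"): PD_IV_WISTAR,
        ("Wistar", "SC", "solution"): PD_SC_WISTAR,
        ("Wistar", "SC", "depot"): PD_DEPOT_WISTAR,
        ("Iar:COP", "SC", "depot"): PD_DEPOT_IAR_COP,
        ("Wistar", "SC", "vehicle"): PD_DEPOT_WISTAR,
        ("Iar:COP", "SC", "vehicle"): PD_DEPOT_IAR_COP,
    }
    try:
        return table[key]
    except KeyError:
        raise KeyError(f"no published PD parameter set for arm {key}") from None
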