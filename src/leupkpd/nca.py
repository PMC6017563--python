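"""Non-compartmental analysis and effect-curve (AUEC) summaries.

NCA follows the standard model-free recipe: C_max/T_max by inspection,
AUC by the linear trapezoidal rule with a C_last/k tail extrapolation,
the terminal rate constant k from a log-linear regression of the last
positive observations, t_1/2 = 0.693/k, CL = dose/AUC_0-inf, V_d = CL/k,
and bioavailability F as the AUC ratio against an IV reference.

Because testosterone is an endogenous marker with a non-zero baseline, its
effect curve is summarised by baseline-corrected AUECs: the curve minus
baseline is integrated trapezoidally without tail extrapolation, segments
that cross the baseline are split at the interpolated crossing time, and
the supra-baseline (positive, the flare) and sub-baseline (negative, the
suppression) areas are reported separately.

Group comparisons use the Mann-Whitney U test; for the small samples of
the rat study (n = 5 per group) the exact permutation distribution is
enumerated, with a tie-corrected normal approximation above combined
n = 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .pk import ConcSeries, Dose, ParameterError

__all__ = [
    "NCAResult",
    "AUECResult",
    "auc_trapezoid",
    "estimate_k",
    "nca_summary",
    "bioavailability",
    "aeuc_decompose",
    "compare_groups",
    "EXACT_N_LIMIT",
]

#: Largest combined sample size for which the exact permutation
#: distribution of U is enumerated.
EXACT_N_LIMIT = 20

#: The half-life conversion constant as conventionally rounded in NCA
#: reports: t_1/2 = 0.693 / k.
LN2_NCA = 0.693


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental PK summary for one profile."""

    C_max: float
    T_max: float
    AUC_0_t: float
    AUC_0_inf: float
    k: float
    t_half: float
    CL: float
    V_d: float
    F: float | None = None

    def as_dict(self) -> dict:
        return {
            "C_max": self.C_max,
            "T_max": self.T_max,
            "AUC_0_t": self.AUC_0_t,
            "AUC_0_inf": self.AUC_0_inf,
            "k": self.k,
            "t_half": self.t_half,
            "CL": self.CL,
            "V_d": self.V_d,
            "F": self.F,
        }


@dataclass(frozen=True)
class AUECResult:
    """Baseline-decomposed area under the effect curve."""

    baseline: float
    total_AUEC: float
    positive_AUEC: float
    negative_AUEC: float

    def as_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "total_AUEC": self.total_AUEC,
            "positive_AUEC": self.positive_AUEC,
            "negative_AUEC": self.negative_AUEC,
        }


def auc_trapezoid(
    series: ConcSeries, extrapolate: bool = False, k: float | None = None
) -> dict:
    """Linear-trapezoid AUC from the first to the last observation.

    With ``extrapolate=True`` the tail C_last/k is added to give AUC_0-inf
    (requires k > 0 and a positive final concentration).
    """
    if len(series) < 2:
        raise ParameterError("AUC needs at least 2 points")
    auc_t = float(np.trapezoid(series.values, series.times))
    out = {"AUC_0_t": auc_t}
    if extrapolate:
        if k is None or not (k > 0):
            raise ParameterError("extrapolation requires a terminal k > 0")
        c_last = float(series.values[-1])
        if not (c_last > 0):
            raise ParameterError("extrapolation requires a positive last value")
        out["AUC_0_inf"] = auc_t + c_last / k
    return out


def estimate_k(series: ConcSeries, terminal_points: int = 3) -> float:
    """Terminal elimination rate: -slope of ln C vs t over the last points.

    Uses the last ``terminal_points`` strictly positive observations
    (default 3).
    """
    pos = series.values > 0
    if int(pos.sum()) < 2:
        raise ParameterError("need at least 2 positive concentrations")
    n = min(terminal_points, int(pos.sum()))
    if n < 2:
        raise ParameterError("terminal window must contain at least 2 points")
    t = series.times[pos][-n:]
    logc = np.log(series.values[pos][-n:])
    slope = np.polyfit(t, logc, 1)[0]
    k = -float(slope)
    if not (k > 0):
        raise ParameterError(
            f"terminal phase is not declining (estimated k = {k:.4g} h^-1)"
        )
    return k


def bioavailability(auc_test: float, auc_reference: float) -> float:
    """F (%) = 100 * AUC_0-inf(test route) / AUC_0-inf(IV reference)."""
    if not (auc_reference > 0) or not (auc_test >= 0):
        raise ParameterError("AUC values must be positive")
    return 100.0 * auc_test / auc_reference


def nca_summary(
    series: ConcSeries,
    dose: Dose,
    reference_auc: float | None = None,
    terminal_points: int = 3,
) -> NCAResult:
    """Full non-compartmental summary of one concentration profile.

    ``reference_auc`` (the IV AUC_0-inf) enables the bioavailability
    estimate for extravascular routes.
    """
    imax = int(np.argmax(series.values))
    c_max = float(series.values[imax])
    t_max = float(series.times[imax])
    k = estimate_k(series, terminal_points)
    aucs = auc_trapezoid(series, extrapolate=True, k=k)
    auc_inf = aucs["AUC_0_inf"]
    cl = dose.amount / auc_inf
    f = None
    if reference_auc is not None:
        f = bioavailability(auc_inf, reference_auc)
    return NCAResult(
        C_max=c_max,
        T_max=t_max,
        AUC_0_t=aucs["AUC_0_t"],
        AUC_0_inf=auc_inf,
        k=k,
        t_half=LN2_NCA / k,
        CL=cl,
        V_d=cl / k,
        F=f,
    )


def aeuc_decompose(series: ConcSeries, baseline: float) -> AUECResult:
    """Decompose the effect curve into positive and negative AUECs.

    The baseline-subtracted curve is integrated by the linear trapezoidal
    rule without tail extrapolation; segments crossing the baseline are
    split at the interpolated crossing time.  ``positive_AUEC`` collects
    supra-baseline area (the flare), ``negative_AUEC`` sub-baseline area
    with its negative sign (the suppression), and

        positive + negative == total_AUEC - baseline * (t_last - t_first).
    """
    if len(series) < 2:
        raise ParameterError("AUEC needs at least 2 points")
    if baseline < 0:
        raise ParameterError("baseline must be >= 0")
    t = series.times
    e = series.values - baseline
    pos = 0.0
    neg = 0.0
    for i in range(len(t) - 1):
        t0, t1 = float(t[i]), float(t[i + 1])
        e0, e1 = float(e[i]), float(e[i + 1])
        if e0 * e1 < 0.0:  # crosses the baseline inside the segment
            tc = t0 + e0 / (e0 - e1) * (t1 - t0)
            a1 = 0.5 * e0 * (tc - t0)
            a2 = 0.5 * e1 * (t1 - tc)
        else:
            a1 = 0.5 * (e0 + e1) * (t1 - t0)
            a2 = 0.0
        for a in (a1, a2):
            if a > 0.0:
                pos += a
            else:
                neg += a
    total = float(np.trapezoid(series.values, t))
    return AUECResult(
        baseline=baseline, total_AUEC=total, positive_AUEC=pos, negative_AUEC=neg
    )


def _u_statistic(ranks_sum: float, n1: int) -> float:
    return ranks_sum - n1 * (n1 + 1) / 2.0


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of group a, two-sided p).

    For combined n <= 20 the permutation distribution of U is enumerated
    exactly over all group relabellings (midranks handle ties), and the
    two-sided p is twice the smaller tail, capped at 1.  Larger samples
    fall back to the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ParameterError("each group needs at least one value")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(float(ranks[:n1].sum()), n1)

    if np.ptp(pooled) == 0.0:  # every value tied across both groups
        return u_obs, 1.0

    if n1 + n2 <= EXACT_N_LIMIT:
        total = math.comb(n1 + n2, n1)
        eps = 1e-9
        n_le = 0
        n_ge = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(sum(ranks[i] for i in idx), n1)
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return u_obs, p

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
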