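"""Testosterone turnover pharmacodynamics.

Baseline model: testosterone R is produced at a zero-order rate k_in and
lost first-order at k_out, so dR/dt = k_in - k_out * R relaxes to the
asymptote k_in/k_out from the observed baseline R0.

Drug-effect (feedback tolerance) model: leuprolide, a GnRH super-agonist,
first *stimulates* testosterone production (the flare) through a Hill term
C_E = E_max * C^h / (C^h + EC_50^h), while a feedback compartment F
modulates production so that sustained stimulation depletes F and the
response then falls below baseline (the therapeutic suppression):

    dR/dt = (1 + C_E) * k_in * F - k_out * R
    dF/dt = k_f_on / R - k_f_off * F        (reciprocal feedback, default)

The reciprocal form makes the feedback inhibitory -- high testosterone
slows the replenishment of F -- which is what produces suppression below
baseline after the flare.  A literal product form ``k_f_on * R`` is
positive feedback and cannot suppress; it is retained behind
``feedback_form="product"`` for sensitivity checks only.

F is initialised at F0 = k_out * R0 / k_in so that dR/dt = 0 at t = 0 in
the absence of drug.  Note this pins only the R-equation; (R0, F0) is a
fixed point of the *joint* system only when k_f_on = k_f_off * F0 * R0
holds, and published parameter sets need not satisfy it exactly.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .ode import DEFAULT_STEP, OdeSystem, integrate
from .pk import ConcSeries, ParameterError, PKSystem, _times_array

__all__ = [
    "PDParams",
    "PDModelError",
    "hill_effect",
    "simulate_baseline",
    "initial_feedback_state",
    "simulate_pd",
    "linked_system",
    "FEEDBACK_FORMS",
]

FEEDBACK_FORMS = ("reciprocal", "product")

DrugInput = Union[None, ConcSeries, PKSystem, Callable[[float], float]]


class PDModelError(RuntimeError):
    """The PD simulation became pathological (e.g. response hit zero)."""


@dataclass(frozen=True)
class PDParams:
    """Turnover, feedback and Hill-effect constants.

    k_in    : zero-order production rate (response-units/h, scaled by F)
    k_out   : first-order loss rate (h^-1)
    k_f_on  : feedback onset constant (h^-1 * ng/mL under the reciprocal form)
    k_f_off : feedback offset constant (h^-1)
    E_max   : maximum stimulation capacity (dimensionless)
    EC_50   : leuprolide concentration at half-maximal effect (ng/mL)
    h       : Hill coefficient
    R0      : baseline testosterone (ng/mL)
    """

    k_in: float
    k_out: float
    k_f_on: float
    k_f_off: float
    E_max: float
    EC_50: float
    h: float
    R0: float

    def __post_init__(self) -> None:
        for name in ("k_in", "k_out", "k_f_on", "k_f_off", "EC_50", "h", "R0"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
        if self.E_max < 0 or not math.isfinite(self.E_max):
            raise ParameterError(f"E_max must be finite and >= 0, got {self.E_max}")


def hill_effect(C, params: PDParams):
    """Hill stimulation C_E = E_max * C^h / (C^h + EC_50^h), in [0, E_max)."""
    c = np.asarray(C, dtype=float)
    if np.any(c < 0):
        raise ParameterError("concentration must be >= 0")
    ch = np.power(c, params.h)
    out = params.E_max * ch / (ch + params.EC_50 ** params.h)
    return float(out) if np.isscalar(C) or np.ndim(C) == 0 else out


def simulate_baseline(params: PDParams, times: Sequence[float]) -> ConcSeries:
    """Drug-free turnover: R(t) = k_in/k_out + (R0 - k_in/k_out) exp(-k_out t)."""
    t = _times_array(times)
    rss = params.k_in / params.k_out
    values = rss + (params.R0 - rss) * np.exp(-params.k_out * t)
    return ConcSeries("testosterone", t, values, {"model": "baseline"})


def initial_feedback_state(params: PDParams) -> float:
    """F0 = k_out * R0 / k_in: zeroes dR/dt at t = 0 with no drug on board."""
    return params.k_out * params.R0 / params.k_in


def _interpolator(series: ConcSeries) -> Callable[[float], float]:
    """Scalar linear interpolant over a ConcSeries (constant beyond the ends)."""
    ts = series.times.tolist()
    vs = series.values.tolist()

    def conc(t: float) -> float:
        if t <= ts[0]:
            return vs[0]
        if t >= ts[-1]:
            return vs[-1]
        i = bisect_right(ts, t)
        t0, t1 = ts[i - 1], ts[i]
        v0, v1 = vs[i - 1], vs[i]
        return v0 + (v1 - v0) * (t - t0) / (t1 - t0)

    return conc


def _feedback_terms(params: PDParams, feedback_form: str):
    if feedback_form not in FEEDBACK_FORMS:
        raise ParameterError(
            f"feedback_form must be one of {FEEDBACK_FORMS}, got {feedback_form!r}"
        )
    kfon, kfoff = params.k_f_on, params.k_f_off
    if feedback_form == "reciprocal":
        return lambda r, f: kfon / r - kfoff * f
    return lambda r, f: kfon * r - kfoff * f


def _driven_system(
    params: PDParams, conc: Callable[[float], float], feedback_form: str
) -> OdeSystem:
    kin, kout = params.k_in, params.k_out
    emax, ec50h, hill = params.E_max, params.EC_50 ** params.h, params.h
    df = _feedback_terms(params, feedback_form)

    def rhs(t, y):
        r, f = y
        if r <= 0.0:
            raise PDModelError(
                f"testosterone response hit zero at t = {t:.4g} h; "
                "pathological parameter set"
            )
        c = conc(t)
        ch = c ** hill if c > 0.0 else 0.0
        ce = emax * ch / (ch + ec50h)
        return ((1.0 + ce) * kin * f - kout * r, df(r, f))

    return OdeSystem(["R", "F"], rhs)


def linked_system(
    params: PDParams, pk: PKSystem, feedback_form: str = "reciprocal"
) -> tuple[OdeSystem, list]:
    """Joint PK-PD system: the PK states followed by R and F.

    Integrating jointly avoids interpolation error in the drug input and is
    how the fitting layer evaluates the model.
    """
    kin, kout = params.k_in, params.k_out
    emax, ec50h, hill = params.E_max, params.EC_50 ** params.h, params.h
    df = _feedback_terms(params, feedback_form)
    vd = pk.V_d
    pidx = pk.plasma_index
    pk_rhs = pk.system.rhs
    n_pk = len(pk.system.state_names)

    def rhs(t, y):
        ypk = y[:n_pk]
        dpk = pk_rhs(t, ypk)
        r, f = y[n_pk], y[n_pk + 1]
        if r <= 0.0:
            raise PDModelError(
                f"testosterone response hit zero at t = {t:.4g} h; "
                "pathological parameter set"
            )
        c = ypk[pidx] / vd
        ch = c ** hill if c > 0.0 else 0.0
        ce = emax * ch / (ch + ec50h)
        return list(dpk) + [(1.0 + ce) * kin * f - kout * r, df(r, f)]

    system = OdeSystem(
        pk.system.state_names + ["R", "F"],
        rhs,
        events=list(pk.system.events),
        breakpoints=list(pk.system.breakpoints),
    )
    y0 = list(pk.y0) + [params.R0, initial_feedback_state(params)]
    return system, y0


def simulate_pd(
    params: PDParams,
    drug: DrugInput,
    times: Sequence[float],
    step: float = DEFAULT_STEP,
    feedback_form: str = "reciprocal",
) -> ConcSeries:
    """Simulate the testosterone response to a leuprolide exposure.

    ``drug`` may be ``None`` (no drug), a callable C(t), a leuprolide
    :class:`ConcSeries` (linearly interpolated between its points), or a
    :class:`PKSystem` handle, in which case PK and PD are integrated
    jointly.
    """
    t = _times_array(times)
    if isinstance(drug, PKSystem):
        system, y0 = linked_system(params, drug, feedback_form)
        ridx = len(system.state_names) - 2
    else:
        if drug is None:
            conc = lambda t_: 0.0
        elif isinstance(drug, ConcSeries):
            conc = _interpolator(drug)
        elif callable(drug):
            conc = drug
        else:
            raise ParameterError(
                f"unsupported drug input of type {type(drug).__name__}"
            )
        system = _driven_system(params, conc, feedback_form)
        y0 = [params.R0, initial_feedback_state(params)]
        ridx = 0
    traj = integrate(system, y0, t, step=step)
    return ConcSeries(
        "testosterone",
        t,
        np.maximum(traj[:, ridx], 0.0),
        {"model": "feedback-turnover", "feedback_form": feedback_form, "step": step},
    )
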