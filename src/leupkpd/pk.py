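"""Leuprolide pharmacokinetic models.

Two model families:

* **Solution** -- a one-compartment model with first-order elimination
  (k = CL/V_d), dosed either IV (bolus into plasma) or SC (first-order
  absorption k_a from an injection-site compartment; Bateman solution).

* **Sustained-release depot** -- the injected microsphere dose is split into
  three sections: a non-encapsulated fraction N_R absorbed like the
  solution (rate k_a), a diffusion-release fraction D_R released at k_d
  after a lag t_lag_d, and an erosive fraction E_R that traverses a chain
  of ES_n transit compartments at rate k_t after a lag t_lag_e (the chain
  yields the gamma-shaped slow-release phase).  Disposition reuses the
  solution-group CL and V_d.

All amounts are in ng, volumes in mL, times in hours, concentrations in
ng/mL.  Lag times are realised as release gating: the release rate terms
are multiplied by an indicator ``t >= t_lag``, keeping the system
ODE-representable; the gate instants are registered as solver breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .ode import DEFAULT_STEP, DoseEvent, OdeSystem, integrate

__all__ = [
    "SolutionPKParams",
    "DepotParams",
    "Dose",
    "ConcSeries",
    "PKSystem",
    "ParameterError",
    "simulate_iv",
    "solution_closed_form",
    "simulate_sc_solution",
    "simulate_depot",
    "depot_release_profile",
    "iv_system",
    "sc_solution_system",
    "depot_system",
    "FRACTION_TOL",
]

#: Tolerance on the release-fraction closure N_R + D_R + E_R = 1.
FRACTION_TOL = 1e-9

ROUTES = ("IV", "SC-solution", "SC-depot")


class ParameterError(ValueError):
    """A parameter set violates its structural constraints."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ParameterError(f"{name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class SolutionPKParams:
    """One-compartment solution-model constants.

    k_a : first-order absorption rate (h^-1); ``None`` for IV dosing.
    CL  : total clearance (mL/h); apparent (CL/F) for SC routes.
    V_d : volume of distribution (mL); apparent for SC routes.
    """

    k_a: float | None
    CL: float
    V_d: float

    def __post_init__(self) -> None:
        _require_positive(CL=self.CL, V_d=self.V_d)
        if self.k_a is not None:
            _require_positive(k_a=self.k_a)

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V_d (h^-1)."""
        return self.CL / self.V_d

    def require_absorption(self) -> float:
        if self.k_a is None:
            raise ParameterError("k_a is required for subcutaneous simulation")
        return self.k_a


@dataclass(frozen=True)
class DepotParams:
    """Three-section sustained-release depot constants.

    The release fractions must close: N_R + D_R + E_R = 1.
    """

    N_R: float
    D_R: float
    E_R: float
    k_d: float
    k_t: float
    t_lag_d: float
    t_lag_e: float
    ES_n: int = 2

    def __post_init__(self) -> None:
        for name in ("N_R", "D_R", "E_R"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        residual = self.N_R + self.D_R + self.E_R - 1.0
        if abs(residual) > FRACTION_TOL:
            raise ParameterError(
                "release fractions must sum to 1 "
                f"(N_R + D_R + E_R - 1 = {residual:+.3e})"
            )
        _require_positive(k_d=self.k_d, k_t=self.k_t)
        if self.t_lag_d < 0 or self.t_lag_e < 0:
            raise ParameterError("lag times must be >= 0")
        if not (1 <= int(self.ES_n) <= 10) or int(self.ES_n) != self.ES_n:
            raise ParameterError(
                f"ES_n must be an integer between 1 and 10, got {self.ES_n}"
            )


@dataclass(frozen=True)
class Dose:
    """An administered leuprolide dose.

    ``amount`` is the absolute dose in ng; ``from_nominal`` builds it from
    the study's mg/kg dosing and a body weight.
    """

    amount: float
    route: str
    nominal_mg_per_kg: float | None = None
    body_weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ParameterError(f"route must be one of {ROUTES}, got {self.route!r}")
        _require_positive(amount=self.amount)

    @classmethod
    def from_nominal(
        cls, nominal_mg_per_kg: float, body_weight_kg: float, route: str
    ) -> "Dose":
        _require_positive(
            nominal_mg_per_kg=nominal_mg_per_kg, body_weight_kg=body_weight_kg
        )
        amount = nominal_mg_per_kg * body_weight_kg * 1e6  # mg -> ng
        return cls(amount, route, nominal_mg_per_kg, body_weight_kg)


@dataclass
class ConcSeries:
    """A time-ordered analyte concentration profile (one subject or a mean)."""

    analyte: str
    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ParameterError("times and values must be 1-D and equally long")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ParameterError("negative concentrations are not allowed")

    def __len__(self) -> int:
        return int(self.times.size)


class PKSystem(NamedTuple):
    """An ODE realisation of a PK model, ready for (joint) integration."""

    system: OdeSystem
    y0: list
    V_d: float
    plasma_index: int


def _times_array(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ParameterError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ParameterError("times must be >= 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ParameterError("times must be strictly increasing")
    return t


# ---------------------------------------------------------------------------
# closed forms


def simulate_iv(
    params: SolutionPKParams, dose: Dose, times: Sequence[float]
) -> ConcSeries:
    """IV bolus: C(t) = (amount/V_d) * exp(-k t), with C(0+) = amount/V_d."""
    if dose.route != "IV":
        raise ParameterError(f"simulate_iv needs an IV dose, got {dose.route!r}")
    t = _times_array(times)
    c0 = dose.amount / params.V_d
    values = c0 * np.exp(-params.k * t)
    return ConcSeries("leuprolide", t, values, {"route": "IV", "model": "closed-form"})


def solution_closed_form(
    params: SolutionPKParams, dose: Dose, times: Sequence[float]
) -> ConcSeries:
    """Bateman solution of first-order absorption and elimination.

    C(t) = amount * k_a / (V_d (k_a - k)) * (exp(-k t) - exp(-k_a t)).
    When k_a == k within 1e-9 relative, the confluent limit
    C(t) = amount * k * t * exp(-k t) / V_d is used.
    """
    if dose.route != "SC-solution":
        raise ParameterError(
            f"solution_closed_form needs an SC-solution dose, got {dose.route!r}"
        )
    ka = params.require_absorption()
    k = params.k
    t = _times_array(times)
    if abs(ka - k) <= 1e-9 * max(ka, k):
        values = dose.amount * k * t * np.exp(-k * t) / params.V_d
    else:
        values = (
            dose.amount * ka / (params.V_d * (ka - k))
            * (np.exp(-k * t) - np.exp(-ka * t))
        )
    values = np.maximum(values, 0.0)  # guard round-off at t ~ 0
    return ConcSeries(
        "leuprolide", t, values, {"route": "SC-solution", "model": "closed-form"}
    )


# ---------------------------------------------------------------------------
# ODE realisations


def iv_system(params: SolutionPKParams, dose: Dose) -> PKSystem:
    """States: A_p (plasma amount), Eliminated.  IV bolus into A_p."""
    if dose.route != "IV":
        raise ParameterError(f"iv_system needs an IV dose, got {dose.route!r}")
    k = params.k

    def rhs(t, y):
        elim = k * y[0]
        return (-elim, elim)

    system = OdeSystem(
        ["A_p", "Eliminated"], rhs, events=[DoseEvent(0.0, "A_p", dose.amount)]
    )
    return PKSystem(system, [0.0, 0.0], params.V_d, plasma_index=0)


def sc_solution_system(params: SolutionPKParams, dose: Dose) -> PKSystem:
    """States: Drug (injection site), A_p, Eliminated."""
    if dose.route != "SC-solution":
        raise ParameterError(
            f"sc_solution_system needs an SC-solution dose, got {dose.route!r}"
        )
    ka = params.require_absorption()
    k = params.k

    def rhs(t, y):
        absorbed = ka * y[0]
        elim = k * y[1]
        return (-absorbed, absorbed - elim, elim)

    system = OdeSystem(
        ["Drug", "A_p", "Eliminated"],
        rhs,
        events=[DoseEvent(0.0, "Drug", dose.amount)],
    )
    return PKSystem(system, [0.0, 0.0, 0.0], params.V_d, plasma_index=1)


def depot_system(
    depot: DepotParams, pk: SolutionPKParams, dose: Dose
) -> PKSystem:
    """Three-section depot model as an ODE system.

    States: NS, DS, ES_1..ES_n, A_p, Eliminated.  The dose splits at t = 0
    into N_R/D_R/E_R shares of the three sections; DS release and the whole
    erosive chain (including its plasma hand-off) are gated until their lag
    times.
    """
    if dose.route != "SC-depot":
        raise ParameterError(f"depot_system needs an SC-depot dose, got {dose.route!r}")
    ka = pk.require_absorption()
    k = pk.k
    kd, kt = depot.k_d, depot.k_t
    tld, tle = depot.t_lag_d, depot.t_lag_e
    n = int(depot.ES_n)

    def rhs(t, y):
        out = [0.0] * (n + 4)
        rel_ns = ka * y[0]
        rel_ds = kd * y[1] if t >= tld else 0.0
        out[0] = -rel_ns
        out[1] = -rel_ds
        if t >= tle:
            prev = 0.0
            for i in range(n):
                flow = kt * y[2 + i]
                out[2 + i] = prev - flow
                prev = flow
            rel_es = prev
        else:
            rel_es = 0.0
        elim = k * y[2 + n]
        out[2 + n] = rel_ns + rel_ds + rel_es - elim
        out[3 + n] = elim
        return out

    names = ["NS", "DS"] + [f"ES_{i + 1}" for i in range(n)] + ["A_p", "Eliminated"]
    events = [
        DoseEvent(0.0, "NS", depot.N_R * dose.amount),
        DoseEvent(0.0, "DS", depot.D_R * dose.amount),
        DoseEvent(0.0, "ES_1", depot.E_R * dose.amount),
    ]
    system = OdeSystem(names, rhs, events=events, breakpoints=[tld, tle])
    return PKSystem(system, [0.0] * (n + 4), pk.V_d, plasma_index=n + 2)


def _simulate(handle: PKSystem, times: Sequence[float], step: float) -> ConcSeries:
    t = _times_array(times)
    traj = integrate(handle.system, handle.y0, t, step=step)
    values = traj[:, handle.plasma_index] / handle.V_d
    return ConcSeries("leuprolide", t, np.maximum(values, 0.0), {})


def simulate_sc_solution(
    params: SolutionPKParams,
    dose: Dose,
    times: Sequence[float],
    step: float = DEFAULT_STEP,
) -> ConcSeries:
    """SC solution profile via the RK4 path (matches the Bateman closed form)."""
    series = _simulate(sc_solution_system(params, dose), times, step)
    series.meta.update({"route": "SC-solution", "model": "rk4", "step": step})
    return series


def simulate_depot(
    depot: DepotParams,
    pk: SolutionPKParams,
    dose: Dose,
    times: Sequence[float],
    step: float = DEFAULT_STEP,
) -> ConcSeries:
    """Sustained-release depot profile via the RK4 path."""
    series = _simulate(depot_system(depot, pk, dose), times, step)
    series.meta.update({"route": "SC-depot", "model": "rk4", "step": step})
    return series


def depot_release_profile(
    depot: DepotParams, times: Sequence[float], k_a: float
) -> np.ndarray:
    """Cumulative fraction of the dose released from the depot by time t.

    Analytic section-wise release CDFs weighted by the section fractions:
    the non-encapsulated section releases as ``1 - exp(-k_a t)``, the
    diffusive section as ``1 - exp(-k_d (t - t_lag_d))`` after its lag, and
    the erosive section as the Erlang (ES_n-stage gamma, rate k_t) CDF
    after its lag.  Monotone from 0 with asymptote 1.
    """
    _require_positive(k_a=k_a)
    t = _times_array(times)
    ns = 1.0 - np.exp(-k_a * t)
    td = np.maximum(t - depot.t_lag_d, 0.0)
    ds = 1.0 - np.exp(-depot.k_d * td)
    te = np.maximum(t - depot.t_lag_e, 0.0)
    es = stats.gamma.cdf(te, a=int(depot.ES_n), scale=1.0 / depot.k_t)
    return depot.N_R * ns + depot.D_R * ds + depot.E_R * es


def with_fractions(depot: DepotParams, N_R: float, D_R: float) -> DepotParams:
    """Return a copy with N_R, D_R free and E_R = 1 - N_R - D_R (simplex closure)."""
    return replace(depot, N_R=N_R, D_R=D_R, E_R=1.0 - N_R - D_R)
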