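"""Two-compartment intravenous disposition engine.

The structural model is the classical mammillary two-compartment model for an
intravenously dosed antibody: a central compartment (volume ``vc``, the one
that is sampled) exchanging drug with a peripheral compartment (volume ``vp``)
through the distributional clearance ``q``, with linear elimination clearance
``cl`` from the central compartment and an optional parallel Michaelis-Menten
elimination term (``vm``, ``km``).

All quantities use a per-kilogram convention: amounts in ug/kg, volumes in
mL/kg, clearances in mL/day/kg, concentrations in ug/mL and time in days.
Doses expressed in mg/kg are converted with :data:`MG_TO_UG` at the public
boundary (:meth:`DoseEvent.from_mg`).

For ``vm = 0`` the model is linear and the concentration after an IV bolus is
the biexponential

    C(t) = (D / vc) * [A * exp(-alpha*t) + B * exp(-beta*t)],

with ``A = (alpha - k21)/(alpha - beta)``, ``B = (k21 - beta)/(alpha - beta)``
and ``alpha, beta`` the roots of ``x^2 - (k10+k12+k21) x + k10*k21``.
Multi-dose profiles follow by superposition; zero-order infusions are
integrated analytically. Nonlinear elimination falls back to a stiff-capable
ODE integration of the amounts in both compartments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import NumericError, UnsupportedOperationError, ValidationError

#: conversion applied to doses supplied in mg/kg
MG_TO_UG = 1000.0

#: relative discriminant below which alpha ~ beta and the closed form is
#: numerically unsafe (catastrophic cancellation); the ODE path is used instead
DEGENERACY_RTOL = 1e-12

ODE_RTOL = 1e-8
ODE_ATOL = 1e-10

#: default dense-grid resolution for numeric AUC: points per 28 days
DEFAULT_GRID_PER_28_DAYS = 2000


@dataclass(frozen=True)
class PKParameters:
    """Structural kinetic parameters on a per-kg basis.

    Parameters
    ----------
    cl : float
        Linear elimination clearance, mL/day/kg. ``cl = 0`` is admitted as a
        diagnostic limit (no linear elimination); operations that require
        elimination (terminal half-life, AUC to infinity) reject it.
    q : float
        Inter-compartmental (distributional) clearance, mL/day/kg.
    vc, vp : float
        Central / peripheral volumes of distribution, mL/kg.
    vm : float
        Maximal rate of the optional Michaelis-Menten elimination,
        ug/day/kg. ``vm = 0`` (default) selects the linear model.
    km : float
        Michaelis constant, ug/mL.
    """

    cl: float
    q: float
    vc: float
    vp: float
    vm: float = 0.0
    km: float = 5.0

    def __post_init__(self) -> None:
        if not (self.cl >= 0):
            raise ValidationError(f"cl must be >= 0, got {self.cl}")
        if not (self.q >= 0):
            raise ValidationError(f"q must be >= 0, got {self.q}")
        if not (self.vc > 0):
            raise ValidationError(f"vc must be > 0, got {self.vc}")
        if not (self.vp > 0):
            raise ValidationError(f"vp must be > 0, got {self.vp}")
        if not (self.vm >= 0):
            raise ValidationError(f"vm must be >= 0, got {self.vm}")
        if not (self.km > 0):
            raise ValidationError(f"km must be > 0, got {self.km}")

    @property
    def is_linear(self) -> bool:
        return self.vm == 0.0

    def replace(self, **changes) -> "PKParameters":
        return _dc_replace(self, **changes)


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous dose into the central compartment.

    ``duration = 0`` is an instantaneous bolus; ``duration > 0`` a zero-order
    infusion of the same total ``amount``.
    """

    time: float
    amount: float  # ug/kg
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not (self.time >= 0):
            raise ValidationError(f"dose time must be >= 0, got {self.time}")
        if not (self.amount > 0):
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if not (self.duration >= 0):
            raise ValidationError(f"dose duration must be >= 0, got {self.duration}")

    @classmethod
    def from_mg(cls, time: float, amount_mg: float, duration: float = 0.0) -> "DoseEvent":
        """Build a dose from an amount in mg/kg (converted x1000 to ug/kg)."""
        return cls(time=time, amount=amount_mg * MG_TO_UG, duration=duration)


@dataclass(frozen=True)
class MicroRates:
    """First-order micro constants and hybrid disposition rates (1/day)."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment concentration sampled on a strictly increasing grid."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValidationError("times and conc must be 1-D arrays of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("profile times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "conc": self.conc})


def micro_constants(params: PKParameters) -> MicroRates:
    """Micro rate constants and hybrid rates for the linear model.

    ``k10 = cl/vc``, ``k12 = q/vc``, ``k21 = q/vp``; ``alpha >= beta`` are the
    roots of ``x^2 - (k10+k12+k21) x + k10*k21 = 0``. beta is computed from
    the Vieta product ``alpha*beta = k10*k21`` for numerical stability.
    """
    if params.vm > 0:
        raise UnsupportedOperationError(
            "micro-rate constants are defined only for the linear model (vm = 0)"
        )
    k10 = params.cl / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp
    s = k10 + k12 + k21
    p = k10 * k21
    disc = max(s * s - 4.0 * p, 0.0)
    alpha = 0.5 * (s + math.sqrt(disc))
    beta = p / alpha if alpha > 0 else 0.0
    return MicroRates(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


class _DegenerateDisposition(Exception):
    """alpha ~ beta: the biexponential macro-constants are ill-conditioned."""


def _exp_modes(params: PKParameters) -> tuple[tuple[float, float], ...]:
    """Exponential modes ((lambda, coefficient-per-unit-amount), ...).

    A unit bolus produces ``C(t) = sum_i coef_i * exp(-lambda_i t)``.
    Raises :class:`_DegenerateDisposition` when alpha ~ beta.
    """
    mr = micro_constants(params)
    s = mr.alpha + mr.beta
    d = mr.alpha - mr.beta
    if d <= 0 or (s > 0 and (d / s) ** 2 < DEGENERACY_RTOL):
        raise _DegenerateDisposition
    a_coef = (mr.alpha - mr.k21) / d
    b_coef = (mr.k21 - mr.beta) / d
    return ((mr.alpha, a_coef / params.vc), (mr.beta, b_coef / params.vc))


def _cum_exp(lam: float, u: np.ndarray) -> np.ndarray:
    """Integral of exp(-lam*x) from 0 to u (u >= 0 elementwise)."""
    if lam == 0.0:
        return u
    return -np.expm1(-lam * u) / lam


def _linear_profile(params: PKParameters, doses: Sequence[DoseEvent], times: np.ndarray) -> np.ndarray:
    modes = _exp_modes(params)
    conc = np.zeros_like(times, dtype=float)
    for d in doses:
        dt = times - d.time
        active = dt >= 0
        if not np.any(active):
            continue
        u = np.clip(dt, 0.0, None)
        if d.duration == 0.0:
            resp = np.zeros_like(u)
            for lam, c in modes:
                if c == 0.0:
                    continue
                resp += c * np.exp(-lam * u)
            conc += np.where(active, d.amount * resp, 0.0)
        else:
            rate = d.amount / d.duration
            u_end = np.clip(dt - d.duration, 0.0, None)
            resp = np.zeros_like(u)
            for lam, c in modes:
                if c == 0.0:
                    continue
                resp += c * (_cum_exp(lam, u) - _cum_exp(lam, u_end))
            conc += np.where(active, rate * resp, 0.0)
    return conc


def _ode_rhs_factory(params: PKParameters):
    cl, q, vc, vp, vm, km = params.cl, params.q, params.vc, params.vp, params.vm, params.km

    def make(rate: float):
        def rhs(t, y):
            c1 = y[0] / vc
            c2 = y[1] / vp
            flux = q * (c1 - c2)
            elim = cl * c1
            if vm > 0:
                elim += vm * c1 / (km + c1)
            return (rate - elim - flux, flux)

        return rhs

    return make


def _ode_profile(params: PKParameters, doses: Sequence[DoseEvent], times: np.ndarray) -> np.ndarray:
    make_rhs = _ode_rhs_factory(params)
    t0 = min(0.0, float(times[0]), min(d.time for d in doses))
    t_last = max(float(times[-1]), max(d.time + d.duration for d in doses))

    breaks = {t0, t_last}
    bolus_at: dict[float, float] = {}
    infusions: list[DoseEvent] = []
    for d in doses:
        breaks.add(d.time)
        if d.duration > 0:
            infusions.append(d)
            breaks.add(d.time + d.duration)
        else:
            bolus_at[d.time] = bolus_at.get(d.time, 0.0) + d.amount
    bp = sorted(b for b in breaks if t0 <= b <= t_last)

    out = np.zeros_like(times, dtype=float)
    y = np.array([0.0, 0.0])
    for a, b in zip(bp[:-1], bp[1:]):
        if a in bolus_at:
            y = y + np.array([bolus_at[a], 0.0])
        out[times == a] = y[0] / params.vc
        # constant infusion rate over (a, b)
        rate = sum(d.amount / d.duration for d in infusions if d.time <= a < d.time + d.duration)
        inner = times[(times > a) & (times < b)]
        t_eval = np.concatenate([inner, [b]])
        sol = solve_ivp(
            make_rhs(rate), (a, b), y, method="LSODA", t_eval=t_eval,
            rtol=ODE_RTOL, atol=ODE_ATOL,
        )
        if not sol.success:
            raise NumericError(
                f"ODE integration failed on [{a}, {b}]: {sol.message} (params={params})"
            )
        out[(times > a) & (times < b)] = sol.y[0][:-1] / params.vc
        y = sol.y[:, -1]
    last = bp[-1]
    if last in bolus_at:
        y = y + np.array([bolus_at[last], 0.0])
    out[times == last] = y[0] / params.vc
    return np.clip(out, 0.0, None)


def concentration_profile(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    method: str = "auto",
) -> ConcentrationProfile:
    """Central concentration at the requested times for a dosing history.

    ``method`` is ``"auto"`` (closed form when linear and well-conditioned,
    else ODE), ``"closed"`` or ``"ode"``. Times at a dose instant report the
    post-dose concentration, so a bolus ``D`` at ``t=0`` gives
    ``C(0) = D/vc``. Times before the first dose report 0.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if not doses:
        raise ValidationError("at least one dose is required")
    if method not in ("auto", "closed", "ode"):
        raise ValidationError(f"unknown method {method!r}")

    if method == "closed" and not params.is_linear:
        raise UnsupportedOperationError("closed-form solution requires a linear model (vm = 0)")

    if method in ("auto", "closed") and params.is_linear:
        try:
            conc = _linear_profile(params, doses, t)
            return ConcentrationProfile(t, np.clip(conc, 0.0, None))
        except _DegenerateDisposition:
            if method == "closed":
                raise UnsupportedOperationError(
                    "alpha ~ beta: closed form ill-conditioned, use the ODE path"
                )
    return ConcentrationProfile(t, _ode_profile(params, doses, t))


def concentrations_at(
    params: PKParameters, doses: Sequence[DoseEvent], times: Sequence[float], method: str = "auto"
) -> np.ndarray:
    """Concentrations at arbitrary (possibly unsorted/duplicated) times."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.zeros(0)
    uniq, inverse = np.unique(t, return_inverse=True)
    prof = concentration_profile(params, doses, uniq, method=method)
    return prof.conc[inverse].reshape(t.shape)


def _bolus_window_auc(dose: DoseEvent, modes, t_start: float, t_end: float) -> float:
    u2 = t_end - dose.time
    if u2 <= 0:
        return 0.0
    u1 = max(t_start - dose.time, 0.0)
    total = 0.0
    for lam, c in modes:
        if c == 0.0:
            continue
        if lam == 0.0:
            if math.isinf(u2):
                raise ValidationError("AUC diverges: non-decaying mode (cl = 0)")
            total += c * (u2 - u1)
        else:
            e1 = math.exp(-lam * u1)
            e2 = 0.0 if math.isinf(u2) else math.exp(-lam * u2)
            total += c / lam * (e1 - e2)
    return dose.amount * total


def _infusion_cum_auc(dose: DoseEvent, modes, u: float) -> float:
    """Integral of the infusion response from the dose start to offset u >= 0."""
    if u <= 0:
        return 0.0
    T = dose.duration
    rate = dose.amount / T
    total = 0.0
    for lam, c in modes:
        if c == 0.0:
            continue
        if lam == 0.0:
            raise ValidationError("AUC diverges: non-decaying mode (cl = 0)")
        if u <= T:
            total += (c / lam) * (u - (1.0 - math.exp(-lam * u)) / lam)
        else:
            head = (c / lam) * (T - (1.0 - math.exp(-lam * T)) / lam)
            e_tail = 0.0 if math.isinf(u) else math.exp(-lam * (u - T))
            e_full = 0.0 if math.isinf(u) else math.exp(-lam * u)
            head += (c / lam**2) * ((1.0 - e_tail) - (math.exp(-lam * T) - e_full))
            total += head
    return rate * total


def _profile_auc(profile: ConcentrationProfile, t_start: float, t_end: float) -> float:
    t, c = profile.times, profile.conc
    if t_start < t[0] or t_end > t[-1]:
        raise ValidationError(
            f"integration window [{t_start}, {t_end}] outside profile range [{t[0]}, {t[-1]}]"
        )
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inside], [t_end]])
    cc = np.concatenate([
        [np.interp(t_start, t, c)], c[inside], [np.interp(t_end, t, c)]
    ])
    return float(np.trapezoid(cc, tt))


def auc(
    target,
    t_start: float = 0.0,
    t_end: float = 28.0,
    *,
    doses: Sequence[DoseEvent] | None = None,
    method: str | None = None,
    grid_per_28_days: int = DEFAULT_GRID_PER_28_DAYS,
) -> float:
    """Area under the central concentration curve on [t_start, t_end], ug*day/mL.

    ``target`` is either a :class:`ConcentrationProfile` (trapezoid on its own
    grid) or a :class:`PKParameters` with ``doses`` supplied. For parameters,
    ``method="analytic"`` (default for the linear model) integrates each
    exponential term exactly and supports ``t_end = inf``, where
    ``AUC = total dose / cl``; ``method="numeric"`` evaluates the model on a
    dense grid (``grid_per_28_days`` points per 28 days) and applies the
    trapezoid rule.
    """
    if not (t_start >= 0):
        raise ValidationError(f"t_start must be >= 0, got {t_start}")
    if not (t_end > t_start):
        raise ValidationError("t_end must exceed t_start")

    if isinstance(target, ConcentrationProfile):
        if math.isinf(t_end):
            raise ValidationError("t_end must be finite for a sampled profile")
        return _profile_auc(target, t_start, t_end)

    params: PKParameters = target
    if doses is None or not doses:
        raise ValidationError("doses are required when integrating from parameters")
    if method is None:
        method = "analytic" if params.is_linear else "numeric"

    if method == "analytic":
        if not params.is_linear:
            raise UnsupportedOperationError(
                "analytic AUC requires a linear model (vm = 0); use method='numeric'"
            )
        try:
            modes = _exp_modes(params)
        except _DegenerateDisposition:
            if math.isinf(t_end):
                raise UnsupportedOperationError(
                    "alpha ~ beta: analytic AUC(0, inf) unavailable"
                ) from None
            method = "numeric"
        else:
            total = 0.0
            for d in doses:
                if d.duration == 0.0:
                    total += _bolus_window_auc(d, modes, t_start, t_end)
                else:
                    u1 = max(t_start - d.time, 0.0)
                    u2 = t_end - d.time
                    if u2 > 0:
                        total += _infusion_cum_auc(d, modes, u2) - _infusion_cum_auc(d, modes, u1)
            return total

    if math.isinf(t_end):
        raise ValidationError("numeric AUC requires a finite t_end")
    n = max(int(math.ceil(grid_per_28_days * (t_end - t_start) / 28.0)) + 1, 2)
    grid = np.linspace(t_start, t_end, n)
    # boluses make the profile jump: bracket each dose instant inside the
    # window with a pre-dose point so the trapezoid sees both sides
    extra = []
    for d in doses:
        if t_start < d.time < t_end:
            extra += [d.time - 1e-9, d.time] if d.duration == 0 else [d.time]
        if d.duration > 0 and t_start < d.time + d.duration < t_end:
            extra.append(d.time + d.duration)
    if extra:
        grid = np.unique(np.concatenate([grid, extra]))
    prof = concentration_profile(params, doses, grid)
    return float(np.trapezoid(prof.conc, prof.times))


def terminal_halflife(params: PKParameters) -> float:
    """Terminal half-life ln(2)/beta of the linear model, days.

    For the degenerate one-compartment limit ``q = 0`` the peripheral
    compartment is disconnected and the observable decay rate is ``k10``.
    """
    if params.vm > 0:
        raise UnsupportedOperationError("terminal half-life is defined for the linear model only")
    if params.cl <= 0:
        raise ValidationError("terminal half-life requires cl > 0")
    mr = micro_constants(params)
    rate = mr.k10 if params.q == 0 else mr.beta
    return math.log(2.0) / rate
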