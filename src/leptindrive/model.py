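"""Energy-balance model of food intake under leptin feedback.

The model tracks two state variables for one subject: the calories C [cal]
stored in adipose tissue and the plasma leptin concentration L [ng/ml].
Intake is a latent drive D [cal/day] damped by leptin, expenditure Q(t)
decays slowly, and the dynamics are linear::

    dC/dt = (D - alpha*L) - Q(t)
    dL/dt = beta*C - gamma*L
    Q(t)  = Q0 * exp(-eps * t)        (piecewise in eps, Q continuous)

Leptin clearance is fast (gamma ~ 40/day, a half-life of minutes) compared
with weight change (months to years), so L relaxes onto the quasi-steady
state L = beta*C/gamma and the calorie balance reduces to the scalar
equation dC/dt = D - eta*C - Q(t) with eta = alpha*beta/gamma.  For
constant D the reduced equation has the explicit solution

    C(t) = D/eta - Q(t)/(eta - eps)      (valid when eta > eps),

where the integration constant of the homogeneous part is dropped: by the
time the record starts the initial condition has been forgotten.  Weight
follows from the fat store as W = C/(rho*delta), with rho = 3500 cal per
lb of fat and delta the body-fat fraction.

This module holds the parameter container, the literature-anchored
parameter derivations (leptin clearance from its plasma half-life, leptin
production from a reference plasma level, intake damping from the
composite decay rate), the piecewise expenditure, the closed-form weight
trajectory, and the full two-state right-hand side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

from .containers import DAYS_PER_MONTH  # noqa: F401  (re-exported unit constant)
from .errors import ConfigError, DomainError

MINUTES_PER_DAY = 1440.0

#: Caloric density of body fat, cal per lb.
RHO_DEFAULT = 3500.0
#: Reference mean plasma leptin in women, ng/ml.
L_REF_DEFAULT = 20.3


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise DomainError(f"{name} must be strictly positive, got {value!r}")


def gamma_from_halflife(halflife_min: float) -> float:
    """Leptin clearance rate [1/day] from its plasma half-life in minutes.

    Renal clearance with half-life 24.9 min gives gamma = 40.1/day.
    """
    if not (halflife_min > 0):
        raise DomainError(f"half-life must be positive, got {halflife_min!r}")
    return math.log(2.0) / halflife_min * MINUTES_PER_DAY


def beta_from_reference(L_ref: float, gamma: float, rho: float,
                        delta: float, W_ref: float) -> float:
    """Leptin production coefficient beta [ng/ml per cal per day].

    Calibrated so the quasi-steady state beta*C/gamma reproduces the
    reference plasma level ``L_ref`` at the reference fat store
    C = rho*delta*W_ref.
    """
    _require_positive(L_ref=L_ref, gamma=gamma, rho=rho, delta=delta, W_ref=W_ref)
    if not (0 < delta < 1):
        raise DomainError(f"body-fat fraction delta must lie in (0,1), got {delta}")
    return gamma * L_ref / (rho * delta * W_ref)


def alpha_from_eta(eta: float, gamma: float, beta: float) -> float:
    """Intake damping alpha [cal/day per ng/ml] from eta = alpha*beta/gamma."""
    _require_positive(eta=eta, gamma=gamma, beta=beta)
    return eta * gamma / beta


def qss_leptin(C, beta: float, gamma: float):
    """Quasi-steady-state leptin level L = beta*C/gamma for a fat store C."""
    _require_positive(beta=beta, gamma=gamma)
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise DomainError("stored calories C must be non-negative")
    out = beta * C / gamma
    return float(out) if out.ndim == 0 else out


def calories_to_weight(C, rho: float, delta: float):
    """Body weight W = C/(rho*delta) [lb] from the adipose calorie store."""
    _require_positive(rho=rho, delta=delta)
    out = np.asarray(C, dtype=float) / (rho * delta)
    return float(out) if out.ndim == 0 else out


def weight_to_calories(W, rho: float, delta: float):
    """Adipose calorie store C = rho*delta*W [cal]; inverse of calories_to_weight."""
    _require_positive(rho=rho, delta=delta)
    out = rho * delta * np.asarray(W, dtype=float)
    return float(out) if out.ndim == 0 else out


def _check_schedule(epsilons: Sequence[float], transitions: Sequence[float]) -> None:
    if len(epsilons) == 0:
        raise ConfigError("expenditure schedule needs at least one decay rate")
    if len(transitions) != len(epsilons) - 1:
        raise ConfigError(
            f"schedule with {len(epsilons)} rates needs {len(epsilons) - 1} "
            f"transition times, got {len(transitions)}"
        )
    if any(e < 0 for e in epsilons):
        raise DomainError("expenditure decay rates must be non-negative")
    t = np.asarray(transitions, dtype=float)
    if t.size and (np.any(np.diff(t) <= 0) or np.any(t <= 0)):
        raise ConfigError("transition times must be positive and strictly increasing")


def expenditure(t_day, Q0: float, epsilons: Sequence[float],
                transitions: Sequence[float] = ()):
    """Piecewise-exponential expenditure Q(t) [cal/day], continuous everywhere.

    Q(t) = Q0*exp(-eps_1*t) up to the first transition, then continues from
    its value there with the next decay rate, and so on.
    """
    _require_positive(Q0=Q0)
    _check_schedule(epsilons, transitions)
    eps = np.asarray(epsilons, dtype=float)
    trans = np.asarray(transitions, dtype=float)
    t = np.asarray(t_day, dtype=float)
    # expenditure at each section start, chaining continuity
    starts = np.concatenate(([0.0], trans))
    q_start = np.empty(eps.size)
    q_start[0] = Q0
    for i in range(1, eps.size):
        q_start[i] = q_start[i - 1] * np.exp(-eps[i - 1] * (starts[i] - starts[i - 1]))
    idx = np.searchsorted(trans, t, side="right")
    out = q_start[idx] * np.exp(-eps[idx] * (t - starts[idx]))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelParams:
    """All rate constants and scale parameters of the model for one subject.

    Any field may be left ``None`` when a workflow does not need it; the
    cross-field invariants are checked over the fields that are set.
    """

    D: Optional[float] = None            # drive, cal/day
    alpha: Optional[float] = None        # leptin damping of intake, cal/day per ng/ml
    beta: Optional[float] = None         # leptin production, ng/ml per cal per day
    gamma: Optional[float] = None        # leptin clearance, 1/day
    delta: Optional[float] = None        # body-fat fraction, dimensionless
    eta: Optional[float] = None          # composite decay alpha*beta/gamma, 1/day
    Q0: Optional[float] = None           # initial expenditure, cal/day
    epsilons: tuple[float, ...] = ()     # expenditure decay rates, 1/day
    transitions: tuple[float, ...] = ()  # section boundaries, days
    rho: float = RHO_DEFAULT             # cal per lb of body fat
    L_ref: float = L_REF_DEFAULT         # reference plasma leptin, ng/ml
    W_ref: Optional[float] = None        # reference mean weight, lb

    def __post_init__(self) -> None:
        object.__setattr__(self, "epsilons", tuple(float(e) for e in self.epsilons))
        object.__setattr__(self, "transitions", tuple(float(t) for t in self.transitions))
        for name in ("D", "alpha", "beta", "gamma", "eta", "Q0", "rho", "L_ref", "W_ref"):
            value = getattr(self, name)
            if value is not None and not (value > 0):
                raise DomainError(f"{name} must be strictly positive, got {value!r}")
        if self.delta is not None and not (0 < self.delta < 1):
            raise DomainError(f"delta must lie in (0,1), got {self.delta!r}")
        if self.epsilons:
            _check_schedule(self.epsilons, self.transitions)
            if self.eta is not None and self.eta <= max(self.epsilons):
                raise DomainError(
                    f"eta ({self.eta}) must exceed every expenditure decay rate "
                    f"(max {max(self.epsilons)}): the explicit solution requires it"
                )
        if None not in (self.alpha, self.beta, self.gamma, self.eta):
            implied = self.alpha * self.beta / self.gamma
            if not math.isclose(implied, self.eta, rel_tol=1e-9):
                raise DomainError(
                    f"eta={self.eta} inconsistent with alpha*beta/gamma={implied}"
                )

    # -- derived operations ------------------------------------------------

    def with_derived_rates(self) -> "ModelParams":
        """Fill alpha and beta from (eta, gamma, L_ref, W_ref, rho, delta)."""
        for name in ("eta", "gamma", "delta", "W_ref"):
            if getattr(self, name) is None:
                raise ConfigError(f"deriving alpha/beta requires {name}")
        beta = beta_from_reference(self.L_ref, self.gamma, self.rho, self.delta,
                                   self.W_ref)
        alpha = alpha_from_eta(self.eta, self.gamma, beta)
        return replace(self, alpha=alpha, beta=beta)

    def expenditure(self, t_day):
        if self.Q0 is None or not self.epsilons:
            raise ConfigError("expenditure requires Q0 and an epsilon schedule")
        return expenditure(t_day, self.Q0, self.epsilons, self.transitions)

    def qss_leptin(self, C):
        return qss_leptin(C, self.beta, self.gamma)

    def calories_to_weight(self, C):
        return calories_to_weight(C, self.rho, self.delta)

    def weight_to_calories(self, W):
        return weight_to_calories(W, self.rho, self.delta)

    # -- serialization (flat key-value config) -----------------------------

    _SCALARS = ("D", "alpha", "beta", "gamma", "delta", "eta", "Q0",
                "rho", "L_ref", "W_ref")

    def to_dict(self) -> dict:
        out: dict = {}
        for name in self._SCALARS:
            value = getattr(self, name)
            if value is not None:
                out[name] = float(value)
        for i, eps in enumerate(self.epsilons, start=1):
            out[f"epsilon{i}"] = float(eps)
        for i, t in enumerate(self.transitions, start=1):
            key = "t_transition" if len(self.transitions) == 1 else f"t_transition{i}"
            out[key] = float(t)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        data = dict(data)
        kwargs: dict = {}
        for name in cls._SCALARS:
            if name in data:
                kwargs[name] = float(data.pop(name))
        epsilons = []
        i = 1
        while f"epsilon{i}" in data:
            epsilons.append(float(data.pop(f"epsilon{i}")))
            i += 1
        transitions = []
        if "t_transition" in data:
            transitions.append(float(data.pop("t_transition")))
        else:
            i = 1
            while f"t_transition{i}" in data:
                transitions.append(float(data.pop(f"t_transition{i}")))
                i += 1
        if data:
            raise ConfigError(f"unknown parameter keys: {sorted(data)}")
        return cls(epsilons=tuple(epsilons), transitions=tuple(transitions), **kwargs)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"parameter file {path} is not a flat key-value mapping")
        return cls.from_dict(data)


def weight_closed_form(t_day, params: ModelParams):
    """Explicit weight trajectory W(t) [lb] of the reduced calorie balance.

    On each expenditure section, C(t) = D/eta - Q(t)/(eta - eps_section)
    with Q continuous across sections; W = C/(rho*delta).  Valid only when
    eta exceeds every decay rate in the schedule.
    """
    for name in ("D", "eta", "Q0", "delta"):
        if getattr(params, name) is None:
            raise ConfigError(f"weight_closed_form requires {name}")
    if not params.epsilons:
        raise ConfigError("weight_closed_form requires an epsilon schedule")
    if params.eta <= max(params.epsilons):
        raise DomainError(
            f"closed form invalid: eta={params.eta} <= max epsilon="
            f"{max(params.epsilons)}"
        )
    t = np.asarray(t_day, dtype=float)
    Q = expenditure(t, params.Q0, params.epsilons, params.transitions)
    idx = np.searchsorted(np.asarray(params.transitions), t, side="right")
    eps = np.asarray(params.epsilons)[idx]
    C = params.D / params.eta - np.asarray(Q) / (params.eta - eps)
    out = C / (params.rho * params.delta)
    return float(out) if out.ndim == 0 else out


def ode_rhs(state: Sequence[float], t_day: float, params: ModelParams,
            drive_fn: Callable[[float], float]) -> tuple[float, float]:
    """Right-hand side (dC/dt, dL/dt) of the full two-state system."""
    for name in ("alpha", "beta", "gamma", "Q0"):
        if getattr(params, name) is None:
            raise ConfigError(f"ode_rhs requires {name}")
    C, L = state
    D = drive_fn(t_day)
    Q = params.expenditure(t_day)
    dC = (D - params.alpha * L) - Q
    dL = params.beta * C - params.gamma * L
    return dC, dL
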