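"""Least-squares estimation of the energy-balance parameters from a weight record.

The observable curve is the explicit solution of the reduced calorie
balance, which on a single expenditure section collapses to

    W(t) = A - B*exp(-eps*t),
    A = D/(eta*rho*delta),   B = Q0/((eta - eps)*rho*delta).

Only the triple (A, B, eps) is identifiable from weight data alone: any
(D, Q0, delta, eta) with the same (A, B) fits identically.  The optimizer
nevertheless works in the physiological quintuple (D, Q0, delta, eta, eps)
inside literature bounds, because the bounds carry the physiological
information that breaks the scale degeneracy into a plausible region; the
fit is repeated from many Latin-hypercube starting points and the best
local optimum is kept.  After the fit, beta is calibrated from the
reference plasma leptin level at the section's mean observed weight and
alpha follows from eta = alpha*beta/gamma.

The piecewise variant handles a record whose expenditure trend breaks at a
known month: all parameters are estimated on the section before the break,
then held fixed while only the second decay rate eps2 is estimated on the
later section, with the expenditure level continuous at the break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .containers import DAYS_PER_MONTH, WeightSeries
from .errors import ConfigError, DataError, EstimationError
from .model import (ModelParams, alpha_from_eta, beta_from_reference,
                    expenditure, weight_closed_form)

GAMMA_DEFAULT = 40.1          # leptin clearance, 1/day (24.9-min half-life)
MIN_OBSERVATIONS = 6

#: Default parameter bounds: drive and expenditure in cal/day, body-fat
#: fraction dimensionless, composite decay eta in 1/day.  The expenditure
#: decay rate eps is parameterized as a fraction of eta/10, which enforces
#: the closed form's validity condition eta > eps as a hard constraint.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "D": (500.0, 6000.0),
    "Q0": (500.0, 6000.0),
    "delta": (0.15, 0.5),
    "eta": (1e-6, 1e-2),
    "eps_frac": (0.0, 1.0),
}

_EPS_FRAC_SCALE = 0.1         # eps = eps_frac * eta * _EPS_FRAC_SCALE


@dataclass(frozen=True)
class FitResult:
    """Outcome of a weight-trajectory fit."""

    params: ModelParams
    rss: float                    # residual sum of squares, lb^2
    fitted: np.ndarray            # model weights at the observation times, lb
    converged: bool
    n_starts_used: int
    start_rss: tuple[float, ...] = ()   # RSS at each multi-start initial point

    @property
    def plateau(self) -> float:
        """A = D/(eta*rho*delta), the asymptotic weight in lb."""
        p = self.params
        return p.D / (p.eta * p.rho * p.delta)

    @property
    def amplitude(self) -> float:
        """B = Q0/((eta - eps1)*rho*delta), the depth below the plateau in lb."""
        p = self.params
        return p.Q0 / ((p.eta - p.epsilons[0]) * p.rho * p.delta)

    @property
    def epsilon(self) -> float:
        return self.params.epsilons[0]

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rss_lb2": float(self.rss),
            "plateau_lb": float(self.plateau),
            "amplitude_lb": float(self.amplitude),
            "converged": bool(self.converged),
            "n_starts_used": int(self.n_starts_used),
        }


def _validate_series(series: WeightSeries) -> None:
    if len(series) < MIN_OBSERVATIONS:
        raise DataError(
            f"fitting needs at least {MIN_OBSERVATIONS} observations, got {len(series)}"
        )
    if np.ptp(series.weight_lb) == 0:
        raise DataError("weight series is constant; the trend is degenerate")


def _unpack(x: np.ndarray, fix_delta: Optional[float]) -> tuple[float, ...]:
    if fix_delta is None:
        D, Q0, delta, log_eta, frac = x
    else:
        D, Q0, log_eta, frac = x
        delta = fix_delta
    eta = 10.0 ** log_eta
    eps = frac * eta * _EPS_FRAC_SCALE
    return D, Q0, delta, eta, eps


def _residuals(x: np.ndarray, t_day: np.ndarray, w_obs: np.ndarray,
               rho: float, fix_delta: Optional[float]) -> np.ndarray:
    D, Q0, delta, eta, eps = _unpack(x, fix_delta)
    scale = rho * delta
    model = D / (eta * scale) - Q0 * np.exp(-eps * t_day) / ((eta - eps) * scale)
    return model - w_obs


def fit_weight_model(series: WeightSeries, gamma: float = GAMMA_DEFAULT,
                     rho: float = 3500.0, L_ref: float = 20.3,
                     bounds: Optional[dict] = None, n_starts: int = 32,
                     seed: int = 0, fix_delta: Optional[float] = None,
                     days_per_month: float = DAYS_PER_MONTH) -> FitResult:
    """Fit (D, Q0, delta, eta, eps) to a weight record by multi-start least squares.

    Time origin is the first observation of the series.  ``fix_delta`` pins
    the body-fat fraction to a literature value, which removes one direction
    of the scale degeneracy.  Returns the best local optimum over
    ``n_starts`` seeded Latin-hypercube starting points.
    """
    _validate_series(series)
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    t_day = (series.month - series.month[0]) * days_per_month
    w_obs = series.weight_lb

    names = ["D", "Q0", "eta", "eps_frac"] if fix_delta is not None else \
            ["D", "Q0", "delta", "eta", "eps_frac"]
    lo, hi = [], []
    for name in names:
        lo.append(b[name][0])
        hi.append(b[name][1])
    lo, hi = np.asarray(lo), np.asarray(hi)
    i_eta = names.index("eta")
    # eta spans four decades: optimize and sample it on a log10 scale
    lo[i_eta], hi[i_eta] = np.log10(lo[i_eta]), np.log10(hi[i_eta])

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), lo, hi)

    best = None
    start_rss = []
    any_success = False
    args = (t_day, w_obs, rho, fix_delta)
    for x0 in starts:
        start_rss.append(float(np.sum(_residuals(x0, *args) ** 2)))
        try:
            sol = least_squares(_residuals, x0, bounds=(lo, hi), args=args,
                                method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=4000)
        except Exception:
            continue
        any_success = any_success or sol.success
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None or not any_success:
        raise EstimationError("no multi-start optimization converged")

    rss, x = best
    D, Q0, delta, eta, eps = _unpack(x, fix_delta)
    W_ref = float(np.mean(w_obs))
    beta = beta_from_reference(L_ref, gamma, rho, delta, W_ref)
    alpha = alpha_from_eta(eta, gamma, beta)
    params = ModelParams(D=D, alpha=alpha, beta=beta, gamma=gamma, delta=delta,
                         eta=eta, Q0=Q0, epsilons=(eps,), rho=rho,
                         L_ref=L_ref, W_ref=W_ref)
    fitted = np.asarray(weight_closed_form(t_day, params))
    return FitResult(params=params, rss=rss, fitted=fitted, converged=any_success,
                     n_starts_used=n_starts, start_rss=tuple(start_rss))


def fit_piecewise(series: WeightSeries, transition_month: float,
                  gamma: float = GAMMA_DEFAULT, rho: float = 3500.0,
                  L_ref: float = 20.3, bounds: Optional[dict] = None,
                  n_starts: int = 32, seed: int = 0,
                  fix_delta: Optional[float] = None,
                  days_per_month: float = DAYS_PER_MONTH) -> FitResult:
    """Two-regime fit: full estimation before ``transition_month``, then only
    the second expenditure decay rate eps2 after it, with Q continuous at the
    transition."""
    if not (series.month[0] < transition_month < series.month[-1]):
        raise ConfigError(
            f"transition month {transition_month} lies outside the record "
            f"({series.month[0]}..{series.month[-1]})"
        )
    pre = series.section(end_month=transition_month)
    post_mask = series.month >= transition_month
    if not post_mask.any():
        raise DataError("no observations after the transition month")

    first = fit_weight_model(pre, gamma=gamma, rho=rho, L_ref=L_ref, bounds=bounds,
                             n_starts=n_starts, seed=seed, fix_delta=fix_delta,
                             days_per_month=days_per_month)
    p = first.params
    eps1 = p.epsilons[0]
    t_star = (transition_month - series.month[0]) * days_per_month
    Q_star = expenditure(t_star, p.Q0, (eps1,))

    t_post = (series.month[post_mask] - series.month[0]) * days_per_month
    w_post = series.weight_lb[post_mask]
    scale = rho * p.delta
    eps_hi = p.eta * _EPS_FRAC_SCALE

    def resid2(z):
        eps2 = z[0]
        model = p.D / (p.eta * scale) - \
            Q_star * np.exp(-eps2 * (t_post - t_star)) / ((p.eta - eps2) * scale)
        return model - w_post

    best = None
    for frac in (0.05, 0.25, 0.5, 0.75, 0.95):
        sol = least_squares(resid2, [frac * eps_hi], bounds=([0.0], [eps_hi]),
                            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        rss2 = float(2.0 * sol.cost)
        if best is None or rss2 < best[0]:
            best = (rss2, float(sol.x[0]))
    rss2, eps2 = best

    params = ModelParams(D=p.D, alpha=p.alpha, beta=p.beta, gamma=gamma,
                         delta=p.delta, eta=p.eta, Q0=p.Q0,
                         epsilons=(eps1, eps2), transitions=(t_star,),
                         rho=rho, L_ref=L_ref, W_ref=p.W_ref)
    t_all = (series.month - series.month[0]) * days_per_month
    fitted = np.asarray(weight_closed_form(t_all, params))
    return FitResult(params=params, rss=first.rss + rss2, fitted=fitted,
                     converged=first.converged, n_starts_used=first.n_starts_used,
                     start_rss=first.start_rss)
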