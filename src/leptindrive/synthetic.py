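"""Synthetic weight histories with the structure the analysis assumes.

The generator emulates multi-year monthly weight records of the kind the
pipeline is designed for: a slow upward weight trend produced by a gently
decaying calorie expenditure, month-to-month fluctuations produced by a
noisy eating drive, and several dietary periods during which the drive is
reduced — with the reduction allowed to begin before the formal period
start (anticipation) and to end before its formal end (relapse), the
behavioural signature the cross-correlation analysis is built to detect.

The forward model is the quasi-steady-state calorie balance integrated
with a piecewise-constant monthly drive; observation noise is added to the
sampled weights.  Ground truth (the generated drive and the parameters)
is returned alongside the observations so recovery can be tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .containers import DAYS_PER_MONTH, DietSchedule, DriveSeries, WeightSeries
from .errors import ConfigError
from .model import ModelParams, expenditure
from .simulate import integrate_qss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to generate one synthetic subject."""

    n_months: int
    baseline_drive: float            # cal/day
    drive_noise_sd: float            # cal/day
    diet_periods: DietSchedule
    diet_depth: float                # cal/day removed from the drive while dieting
    anticipation_lead: float = 0.0   # months the reduction starts early
    relapse_lead: float = 0.0        # months the reduction ends early
    params: ModelParams = field(default_factory=ModelParams)
    obs_noise_sd: float = 0.0        # lb
    seed: int = 0
    W0_lb: Optional[float] = None    # starting weight; default: quasi-equilibrium

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ConfigError("need at least two months")
        for name in ("drive_noise_sd", "diet_depth", "anticipation_lead",
                     "relapse_lead", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SyntheticRecord:
    """Observations plus ground truth for one generated subject."""

    weights: WeightSeries
    drive: DriveSeries               # the generated (true) monthly drive
    params: ModelParams
    schedule: DietSchedule


def make_drive_profile(spec: ScenarioSpec) -> DriveSeries:
    """Generate the monthly drive: baseline + Gaussian noise, reduced by
    ``diet_depth`` during the (lead-shifted) dietary periods; clipped at 0."""
    rng = np.random.default_rng(spec.seed)
    months = np.arange(spec.n_months, dtype=float)
    drive = spec.baseline_drive + rng.normal(0.0, spec.drive_noise_sd,
                                             size=spec.n_months)
    effective = spec.diet_periods.shifted(start_lead=spec.anticipation_lead,
                                          end_lead=spec.relapse_lead)
    drive = drive - spec.diet_depth * effective.contains(months)
    if np.any(drive < 0):
        logger.warning("generated drive went negative in %d months; clipped at 0",
                       int(np.sum(drive < 0)))
        drive = np.maximum(drive, 0.0)
    return DriveSeries(month=months, drive=drive)


def _piecewise_constant_drive(drive: DriveSeries,
                              days_per_month: float) -> Callable[[float], float]:
    values = drive.drive

    def drive_fn(t_day: float) -> float:
        tau = int(np.clip(np.floor(t_day / days_per_month), 0, values.size - 1))
        return float(values[tau])

    return drive_fn


def make_weight_series(spec: ScenarioSpec,
                       days_per_month: float = DAYS_PER_MONTH) -> SyntheticRecord:
    """Integrate the reduced calorie balance under the generated drive and
    sample it monthly with Gaussian observation noise."""
    p = spec.params
    for name in ("eta", "beta", "gamma", "delta", "Q0"):
        if getattr(p, name) is None:
            raise ConfigError(f"generation requires params.{name}")
    if p.epsilons and p.eta <= max(p.epsilons):
        raise ConfigError("generation requires eta > every expenditure decay rate")

    drive = make_drive_profile(spec)
    drive_fn = _piecewise_constant_drive(drive, days_per_month)
    if spec.W0_lb is not None:
        C0 = p.weight_to_calories(spec.W0_lb)
    else:
        # quasi-equilibrium of the baseline drive; only sensible when the
        # baseline is itself near the equilibrium value for Q0
        C0 = spec.baseline_drive / p.eta - p.Q0 / (p.eta - p.epsilons[0])
    month_grid = np.arange(spec.n_months + 1, dtype=float)
    t_grid = month_grid * days_per_month
    traj = integrate_qss(p, drive_fn, C0, t_grid, switch_times=t_grid[1:-1])

    w = traj.W.copy()
    if spec.obs_noise_sd > 0:
        # independent stream so the drive realization is unaffected by whether
        # observation noise is requested
        obs_rng = np.random.default_rng((spec.seed, 1))
        w = w + obs_rng.normal(0.0, spec.obs_noise_sd, size=w.size)
    weights = WeightSeries(month=month_grid, weight_lb=w)
    return SyntheticRecord(weights=weights, drive=drive, params=p,
                           schedule=spec.diet_periods)


def drive_for_mean_weight(params: ModelParams, W_target: float, t_end_day: float,
                          n_grid: int = 2001) -> float:
    """Constant drive that makes the closed-form weight average ``W_target``
    over [0, t_end_day]."""
    for name in ("eta", "delta", "Q0"):
        if getattr(params, name) is None:
            raise ConfigError(f"drive_for_mean_weight requires params.{name}")
    t = np.linspace(0.0, t_end_day, n_grid)
    Q = np.asarray(expenditure(t, params.Q0, params.epsilons, params.transitions))
    idx = np.searchsorted(np.asarray(params.transitions), t, side="right")
    eps = np.asarray(params.epsilons)[idx]
    mean_term = float(np.trapezoid(Q / (params.eta - eps), t) / t_end_day)
    return params.eta * (W_target * params.rho * params.delta + mean_term)


def calibrate_baseline(spec: ScenarioSpec, W_target: float,
                       mean_over_months: Optional[float] = None) -> float:
    """Baseline drive that makes the *deterministic* record (noise zeroed,
    dietary reductions included) average ``W_target`` lb, over the whole
    record or over its first ``mean_over_months`` months.

    The calorie balance is linear, so the mean weight is affine in the
    baseline; two deterministic runs determine it exactly.
    """
    det = replace(spec, drive_noise_sd=0.0, obs_noise_sd=0.0)

    def mean_w(baseline: float) -> float:
        rec = make_weight_series(replace(det, baseline_drive=baseline))
        w, m = rec.weights.weight_lb, rec.weights.month
        if mean_over_months is not None:
            w = w[m <= mean_over_months]
        return float(np.mean(w))

    b0 = spec.baseline_drive
    b1 = b0 * 1.01 + 1.0
    m0, m1 = mean_w(b0), mean_w(b1)
    return b0 + (W_target - m0) * (b1 - b0) / (m1 - m0)


# -- presets ----------------------------------------------------------------

# Eight and five multi-month dietary periods spread over the record, matching
# the number of periods analysed for the two reference subjects.
_A_PERIODS = ((8, 11), (18, 21), (27, 30), (36, 39), (46, 49),
              (55, 58), (64, 67), (73, 76))
_B_PERIODS = ((6, 9), (20, 23), (34, 37), (50, 53), (66, 69))


def preset(name: str, seed: int = 0) -> ScenarioSpec:
    """Named scenarios emulating the two reference subjects.

    ``subject_A_like``: 80 months, single expenditure decay rate, mean
    weight calibrated to 157.0 lb, drive fluctuation SD 131 cal/day, eight
    dietary periods of mean depth 267 cal/day.  ``subject_B_like``: 80
    months with an expenditure-trend break at month 40 (two decay rates,
    expenditure continuous there), first-section mean weight 127.4 lb,
    drive SD 183, five periods of depth 160.  Both include one month of
    anticipation and one of early relapse around each dietary period.
    """
    if name == "subject_A_like":
        params = ModelParams(gamma=40.1, delta=0.405, eta=2.78e-5, Q0=2571.0,
                             epsilons=(1.00e-7,), W_ref=157.0).with_derived_rates()
        guess = drive_for_mean_weight(params, 157.0, 80 * DAYS_PER_MONTH)
        spec = ScenarioSpec(n_months=80, baseline_drive=guess,
                            drive_noise_sd=131.0,
                            diet_periods=DietSchedule.from_pairs(_A_PERIODS),
                            diet_depth=267.0, anticipation_lead=1.0,
                            relapse_lead=1.0, params=params,
                            obs_noise_sd=1.0, seed=seed, W0_lb=145.0)
        baseline = calibrate_baseline(spec, 157.0)
        return replace(spec, baseline_drive=baseline,
                       params=replace(params, D=baseline))
    if name == "subject_B_like":
        t_star = 40 * DAYS_PER_MONTH
        params = ModelParams(gamma=40.1, delta=0.316, eta=1.17e-4, Q0=2100.0,
                             epsilons=(2.06e-6, 8.30e-7), transitions=(t_star,),
                             W_ref=127.4).with_derived_rates()
        guess = drive_for_mean_weight(params, 127.4, t_star)
        spec = ScenarioSpec(n_months=80, baseline_drive=guess,
                            drive_noise_sd=183.0,
                            diet_periods=DietSchedule.from_pairs(_B_PERIODS),
                            diet_depth=160.0, anticipation_lead=1.0,
                            relapse_lead=1.0, params=params,
                            obs_noise_sd=1.0, seed=seed, W0_lb=120.0)
        baseline = calibrate_baseline(spec, 127.4, mean_over_months=40.0)
        return replace(spec, baseline_drive=baseline,
                       params=replace(params, D=baseline))
    raise ConfigError(f"unknown preset {name!r}; expected 'subject_A_like' "
                      f"or 'subject_B_like'")
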