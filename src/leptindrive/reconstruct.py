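"""Reconstruction of the monthly eating drive from an observed weight record.

With the model parameters known, the reduced calorie balance can be read
backwards: discretizing dC/dt = D - alpha*L - Q month by month (forward
difference, with leptin at its quasi-steady-state value for the observed
weight at the left endpoint) isolates the drive

    D(tau) = rho*delta*(W(tau+1) - W(tau)) / dt
             + alpha*L(tau) + Q(tau),       L(tau) = beta*rho*delta*W(tau)/gamma,

with dt the month length in days.  The result is one drive value per
month, one fewer than the number of weight observations.
"""

from __future__ import annotations

import numpy as np

from .containers import DAYS_PER_MONTH, DietSchedule, DriveSeries, WeightSeries
from .errors import ConfigError, DataError
from .model import ModelParams, expenditure, qss_leptin, weight_to_calories


def reconstruct_drive(series: WeightSeries, params: ModelParams,
                      days_per_month: float = DAYS_PER_MONTH) -> DriveSeries:
    """Recover the monthly drive D(tau) [cal/day] from weights and parameters.

    Each drive value is assigned to the month at the left end of its
    forward difference.
    """
    for name in ("alpha", "beta", "gamma", "delta", "Q0"):
        if getattr(params, name) is None:
            raise ConfigError(f"reconstruction requires params.{name}")
    if not params.epsilons:
        raise ConfigError("reconstruction requires an expenditure schedule")
    if len(series) < 2:
        raise DataError("reconstruction needs at least two weight observations")
    if not (days_per_month > 0):
        raise ConfigError("days_per_month must be positive")

    t_day = (series.month - series.month[0]) * days_per_month
    w = series.weight_lb
    dt = np.diff(t_day)                       # days between observations
    C_left = weight_to_calories(w[:-1], params.rho, params.delta)
    L = qss_leptin(C_left, params.beta, params.gamma)
    Q = expenditure(t_day[:-1], params.Q0, params.epsilons, params.transitions)
    drive = params.rho * params.delta * np.diff(w) / dt + params.alpha * L + Q
    return DriveSeries(month=series.month[:-1], drive=drive, leptin=np.asarray(L))


def drive_summary(drive_series: DriveSeries,
                  schedule: DietSchedule) -> tuple[float, float]:
    """Mean and population SD of the drive over months outside every dietary
    period."""
    outside = ~schedule.contains(drive_series.month)
    if not outside.any():
        raise DataError("every month lies inside a dietary period; "
                        "the outside-diet mean is undefined")
    values = drive_series.drive[outside]
    return float(np.mean(values)), float(np.std(values))
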