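"""Quantifying how dieting and leptin pull down the eating drive.

Starting from a reconstructed monthly drive and a schedule of dietary
periods, this module computes:

* the drive deficit E(tau) = Dbar - D(tau), where Dbar is the mean drive
  over months outside every dietary period (so E averages to zero outside
  the periods by construction and is positive when dieting bites);
* the mean deficit per dietary period, with their overall mean and
  population SD;
* a one-sample, one-sided t-test of the per-period means against zero
  (sample variance, alternative "dieting lowers the drive", i.e. mean > 0);
* the dieting and leptin effects as percentages of Dbar
  (100*Ebar/Dbar and 100*alpha*L_ref/Dbar);
* the cross-correlation X(s) of E with the dietary block indicator B,
  where B(tau) = 1 inside periods and 0 outside, the block is shifted by
  s months (backwards for s < 0) and truncated at the record boundaries,
  and X is normalized so that X(0) = 1.  A peak of X at negative s means
  the deficit anticipates the formal dietary periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .containers import DietSchedule, DriveSeries
from .errors import DataError, DomainError, StatsError
from .reconstruct import drive_summary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeficitSeries:
    """Drive deficit E(tau) = Dbar - D(tau) per month, with the reference
    mean drive outside the dietary periods."""

    month: np.ndarray
    deficit: np.ndarray
    mean_drive_outside: float
    sd_drive_outside: float


@dataclass(frozen=True)
class DietEffectReport:
    """Full summary of the dieting and leptin effects on the drive."""

    deficit: DeficitSeries
    period_means: tuple[float, ...]        # Ebar per dietary period, cal/day
    overall_mean: float                    # mean of the period means, cal/day
    overall_sd: float                      # population SD of the period means
    t_stat: float
    p_value: float                         # one-sided, mean > 0
    pct_dieting: float                     # 100*overall_mean/Dbar
    pct_leptin: float                      # 100*alpha*L_ref/Dbar
    shifts: np.ndarray                     # months
    xcorr: np.ndarray                      # X(s), X(0) = 1

    def to_dict(self) -> dict:
        return {
            "mean_drive_outside_cal_day": self.deficit.mean_drive_outside,
            "sd_drive_outside_cal_day": self.deficit.sd_drive_outside,
            "period_means_cal_day": list(self.period_means),
            "overall_mean_cal_day": self.overall_mean,
            "overall_sd_cal_day": self.overall_sd,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "pct_dieting": self.pct_dieting,
            "pct_dieting_printed": round(self.pct_dieting),
            "pct_leptin": self.pct_leptin,
            "pct_leptin_printed": round(self.pct_leptin, 1),
        }


def drive_deficit(drive_series: DriveSeries, schedule: DietSchedule) -> DeficitSeries:
    """Deficit E(tau) = Dbar - D(tau) over the whole record."""
    if len(drive_series) == 0:
        raise DataError("drive series is empty")
    mean_out, sd_out = drive_summary(drive_series, schedule)
    return DeficitSeries(month=drive_series.month,
                         deficit=mean_out - drive_series.drive,
                         mean_drive_outside=mean_out, sd_drive_outside=sd_out)


def period_statistics(deficit: DeficitSeries, schedule: DietSchedule,
                      ) -> tuple[tuple[float, ...], float, float]:
    """Per-period mean deficits plus their overall mean and population SD.

    A scheduled period containing no drive months is excluded with a warning.
    """
    means = []
    for start, end in schedule.periods:
        mask = (deficit.month >= start) & (deficit.month < end)
        if not mask.any():
            logger.warning("dietary period [%s, %s) contains no drive data; excluded",
                           start, end)
            continue
        means.append(float(np.mean(deficit.deficit[mask])))
    if not means:
        raise DataError("no dietary period overlaps the drive record")
    arr = np.asarray(means)
    return tuple(means), float(np.mean(arr)), float(np.std(arr))


def diet_ttest(period_means: Sequence[float]) -> tuple[float, float]:
    """One-sample, one-sided t-test of the per-period mean deficits against 0.

    Uses the sample (n-1) variance; the alternative is a positive mean,
    i.e. dieting genuinely lowers the drive.
    """
    values = np.asarray(period_means, dtype=float)
    if values.size < 2:
        raise StatsError("t-test needs at least two period means")
    res = stats.ttest_1samp(values, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def effect_percentages(overall_mean_E: float, mean_drive_outside: float,
                       alpha: float, L_ref: float) -> tuple[float, float]:
    """Dieting and leptin effects as percentages of the out-of-diet mean drive."""
    if not (mean_drive_outside > 0):
        raise DomainError("mean drive outside dieting must be positive")
    return (100.0 * overall_mean_E / mean_drive_outside,
            100.0 * alpha * L_ref / mean_drive_outside)


def block_function(schedule: DietSchedule, months_grid: Sequence[float]) -> np.ndarray:
    """Dietary block indicator B(tau) on a month grid: 1 inside periods, else 0."""
    grid = np.asarray(months_grid, dtype=float)
    if grid.size >= 2 and np.any(np.diff(grid) <= 0):
        raise DataError("months grid must be strictly increasing")
    return schedule.contains(grid).astype(float)


def cross_correlation(deficit: DeficitSeries, schedule: DietSchedule,
                      shifts: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation X(s) of the deficit with the shifted dietary block.

    X(s) = sum_tau E(tau)*B(tau - s) / sum_tau E(tau)*B(tau), the sums
    running over the deficit's month grid (the shifted block simply has no
    support beyond the record, so boundary handling is truncation).  The
    normalization makes X(0) = 1 exact.
    """
    shifts = np.asarray(shifts, dtype=float)
    if not np.any(shifts == 0):
        raise StatsError("shift grid must include s = 0 for the normalization")
    E = deficit.deficit
    denom = float(np.sum(E * block_function(schedule, deficit.month)))
    if denom == 0:
        raise StatsError("deficit has zero overlap with the dietary block; "
                         "X(s) normalization undefined")
    X = np.empty(shifts.size)
    for i, s in enumerate(shifts):
        B_shifted = schedule.contains(deficit.month - s).astype(float)
        X[i] = float(np.sum(E * B_shifted)) / denom
    return shifts, X


def smoothed_xcorr_peak(shifts: np.ndarray, X: np.ndarray,
                        window: int = 3) -> float:
    """Shift at which a moving-average-smoothed X(s) peaks (ties -> smallest s)."""
    kernel = np.ones(window) / window
    Xs = np.convolve(X, kernel, mode="same")
    return float(shifts[int(np.argmax(Xs))])


def analyze(drive_series: DriveSeries, schedule: DietSchedule,
            alpha: float, L_ref: float,
            shifts: Optional[Sequence[float]] = None) -> DietEffectReport:
    """Run the full dieting/leptin analysis for one reconstructed drive."""
    if shifts is None:
        shifts = np.arange(-12.0, 13.0)
    deficit = drive_deficit(drive_series, schedule)
    period_means, overall_mean, overall_sd = period_statistics(deficit, schedule)
    t_stat, p_value = diet_ttest(period_means)
    pct_diet, pct_leptin = effect_percentages(
        overall_mean, deficit.mean_drive_outside, alpha, L_ref)
    s, X = cross_correlation(deficit, schedule, shifts)
    return DietEffectReport(deficit=deficit, period_means=period_means,
                            overall_mean=overall_mean, overall_sd=overall_sd,
                            t_stat=t_stat, p_value=p_value,
                            pct_dieting=pct_diet, pct_leptin=pct_leptin,
                            shifts=s, xcorr=X)
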