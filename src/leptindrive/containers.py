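"""Lightweight data containers shared by the modelling and analysis modules.

Conventions used throughout the package: time is measured internally in
days; observation grids are in months from the start of the record
(0-based), converted at the astronomical mean of 365.25/12 days per month;
dietary periods are half-open month intervals [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: Mean month length in days (365.25 / 12); configurable in the operations
#: that convert between month and day grids.
DAYS_PER_MONTH: float = 365.25 / 12


def _as_float_array(x: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise DataError(f"{name} contains a non-finite value at position {bad}")
    return arr


@dataclass(frozen=True)
class WeightSeries:
    """A body-weight record: weight in lb at month indices from record start."""

    month: np.ndarray
    weight_lb: np.ndarray

    def __post_init__(self) -> None:
        month = _as_float_array(self.month, "month")
        weight = _as_float_array(self.weight_lb, "weight_lb")
        if month.size != weight.size:
            raise DataError(
                f"month ({month.size}) and weight_lb ({weight.size}) differ in length"
            )
        if month.size >= 2 and not np.all(np.diff(month) > 0):
            bad = int(np.flatnonzero(np.diff(month) <= 0)[0]) + 1
            raise DataError(f"months must be strictly increasing; violated at row {bad}")
        if np.any(weight <= 0):
            bad = int(np.flatnonzero(weight <= 0)[0])
            raise DataError(f"weights must be positive; violated at row {bad}")
        object.__setattr__(self, "month", month)
        object.__setattr__(self, "weight_lb", weight)

    def __len__(self) -> int:
        return int(self.month.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.month, "weight_lb": self.weight_lb})

    def section(self, start_month: float | None = None,
                end_month: float | None = None) -> "WeightSeries":
        """Sub-series with start <= month < end (either bound may be None)."""
        mask = np.ones(len(self), dtype=bool)
        if start_month is not None:
            mask &= self.month >= start_month
        if end_month is not None:
            mask &= self.month < end_month
        if not mask.any():
            raise DataError("requested section contains no observations")
        return WeightSeries(self.month[mask], self.weight_lb[mask])


@dataclass(frozen=True)
class DriveSeries:
    """Monthly drive D(tau) in cal/day, optionally with the QSS leptin level."""

    month: np.ndarray
    drive: np.ndarray
    leptin: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        month = _as_float_array(self.month, "month")
        drive = _as_float_array(self.drive, "drive")
        if month.size != drive.size:
            raise DataError("month and drive differ in length")
        if month.size >= 2 and not np.all(np.diff(month) > 0):
            raise DataError("months must be strictly increasing")
        object.__setattr__(self, "month", month)
        object.__setattr__(self, "drive", drive)
        if self.leptin is not None:
            leptin = _as_float_array(self.leptin, "leptin")
            if leptin.size != month.size:
                raise DataError("leptin and month differ in length")
            object.__setattr__(self, "leptin", leptin)

    def __len__(self) -> int:
        return int(self.month.size)

    def to_frame(self) -> pd.DataFrame:
        data = {"month": self.month, "drive_cal_day": self.drive}
        if self.leptin is not None:
            data["leptin_ng_ml"] = self.leptin
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DietSchedule:
    """Ordered, non-overlapping dietary periods as half-open [start, end) months."""

    periods: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cleaned = []
        for i, (start, end) in enumerate(self.periods):
            start, end = float(start), float(end)
            if not (start < end):
                raise ConfigError(
                    f"period {i} has start {start} >= end {end}"
                )
            cleaned.append((start, end))
        for i in range(1, len(cleaned)):
            if cleaned[i][0] < cleaned[i - 1][1]:
                raise ConfigError(
                    f"periods {i - 1} and {i} overlap or are unsorted: "
                    f"{cleaned[i - 1]} vs {cleaned[i]}"
                )
        object.__setattr__(self, "periods", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.periods)

    def contains(self, months: Sequence[float] | np.ndarray) -> np.ndarray:
        """Boolean mask: True where the month lies inside any period."""
        months = np.asarray(months, dtype=float)
        inside = np.zeros(months.shape, dtype=bool)
        for start, end in self.periods:
            inside |= (months >= start) & (months < end)
        return inside

    def shifted(self, start_lead: float = 0.0, end_lead: float = 0.0) -> "DietSchedule":
        """Periods with the start moved earlier by ``start_lead`` months and
        the end moved earlier by ``end_lead`` months (degenerate results drop)."""
        moved = []
        for start, end in self.periods:
            s, e = start - start_lead, end - end_lead
            if s < e:
                moved.append((s, e))
        return DietSchedule(tuple(moved))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.periods or np.empty((0, 2)), columns=["start_month", "end_month"]
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[float]]) -> "DietSchedule":
        return cls(tuple((float(a), float(b)) for a, b in pairs))
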