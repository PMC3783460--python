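"""File I/O and the end-to-end pipeline (fit -> reconstruct -> diet stats).

All tabular artifacts are plain CSV; parameter sets are flat key-value
YAML; each pipeline run writes a provenance record (configuration echo,
package version, seed) next to its outputs.  Months are 0-based from the
record start and dietary intervals are half-open [start, end).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .containers import DAYS_PER_MONTH, DietSchedule, DriveSeries, WeightSeries
from .diet_effect import DietEffectReport, analyze
from .errors import ConfigError, DataError
from .fit import FitResult, fit_piecewise, fit_weight_model
from .model import ModelParams
from .reconstruct import reconstruct_drive

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"   # round-trips CSV output at 12 significant digits


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}; "
                        f"found {list(frame.columns)}")
    return frame


def _numeric_column(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.index[values.isna() & frame[column].notna()]
    if len(bad):
        row = int(bad[0])
        raise DataError(f"{path}: non-numeric {column} value "
                        f"{frame[column].iloc[row]!r} at data row {row}")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise DataError(f"{path}: missing {column} value at data row {row}")
    return values.to_numpy(dtype=float)


def read_weight_series(path) -> WeightSeries:
    """Read a weight record CSV with columns ``month,weight_lb``."""
    frame = _read_csv(path, ("month", "weight_lb"))
    month = _numeric_column(frame, "month", path)
    weight = _numeric_column(frame, "weight_lb", path)
    dup = np.flatnonzero(np.diff(month) == 0)
    if dup.size:
        raise DataError(f"{path}: duplicated month {month[dup[0]]:g} "
                        f"at data row {dup[0] + 1}")
    return WeightSeries(month=month, weight_lb=weight)


def write_weight_series(series: WeightSeries, path) -> None:
    series.to_frame().to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_schedule(path) -> DietSchedule:
    """Read a dietary schedule CSV with columns ``start_month,end_month``
    (half-open months); an empty file is a valid empty schedule."""
    frame = _read_csv(path, ("start_month", "end_month"))
    if len(frame) == 0:
        return DietSchedule()
    start = _numeric_column(frame, "start_month", path)
    end = _numeric_column(frame, "end_month", path)
    return DietSchedule.from_pairs(zip(start, end))


def write_schedule(schedule: DietSchedule, path) -> None:
    schedule.to_frame().to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_drive_series(path) -> DriveSeries:
    frame = _read_csv(path, ("month", "drive_cal_day"))
    month = _numeric_column(frame, "month", path)
    drive = _numeric_column(frame, "drive_cal_day", path)
    leptin = None
    if "leptin_ng_ml" in frame.columns:
        leptin = _numeric_column(frame, "leptin_ng_ml", path)
    return DriveSeries(month=month, drive=drive, leptin=leptin)


def write_drive_series(drive: DriveSeries, path) -> None:
    drive.to_frame().to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def write_xcorr(shifts: np.ndarray, xcorr: np.ndarray, path) -> None:
    pd.DataFrame({"shift_month": shifts, "xcorr": xcorr}).to_csv(
        Path(path), index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    weights_path: str
    schedule_path: str
    out_dir: str
    params_path: Optional[str] = None    # skip fitting when given
    transition_month: Optional[float] = None
    fix_delta: Optional[float] = None
    days_per_month: float = DAYS_PER_MONTH
    shift_min: float = -12.0
    shift_max: float = 12.0
    n_starts: int = 32
    seed: int = 0
    log_level: str = "INFO"


@dataclass(frozen=True)
class PipelineResult:
    fit: Optional[FitResult]
    params: ModelParams
    drive: DriveSeries
    report: DietEffectReport
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute fit (or load parameters) -> reconstruct -> diet statistics,
    writing every artifact plus a provenance record to ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    weights = _stage("read-weights", read_weight_series, config.weights_path)
    schedule = _stage("read-schedule", read_schedule, config.schedule_path)

    fit_result: Optional[FitResult] = None
    if config.params_path is not None:
        params = _stage("load-params", ModelParams.from_file, config.params_path)
    elif config.transition_month is not None:
        fit_result = _stage("fit", fit_piecewise, weights, config.transition_month,
                            fix_delta=config.fix_delta, n_starts=config.n_starts,
                            seed=config.seed,
                            days_per_month=config.days_per_month)
        params = fit_result.params
    else:
        fit_result = _stage("fit", fit_weight_model, weights,
                            fix_delta=config.fix_delta, n_starts=config.n_starts,
                            seed=config.seed,
                            days_per_month=config.days_per_month)
        params = fit_result.params

    drive = _stage("reconstruct", reconstruct_drive, weights, params,
                   days_per_month=config.days_per_month)
    shifts = np.arange(config.shift_min, config.shift_max + 1)
    report = _stage("diet-stats", analyze, drive, schedule,
                    alpha=params.alpha, L_ref=params.L_ref, shifts=shifts)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_drive_series(drive, out / "drive.csv")
    write_xcorr(report.shifts, report.xcorr, out / "xcorr.csv")
    params.to_file(out / "params.yaml")
    report_dict = report.to_dict()
    if fit_result is not None:
        report_dict["fit"] = fit_result.to_dict()
    (out / "report.json").write_text(json.dumps(report_dict, indent=2))
    (out / "summary.txt").write_text(_summary_text(params, report))
    provenance = {"package": "leptindrive", "version": __version__,
                  "seed": config.seed, "config": dataclasses.asdict(config)}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return PipelineResult(fit=fit_result, params=params, drive=drive,
                          report=report, out_dir=out)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def _summary_text(params: ModelParams, report: DietEffectReport) -> str:
    lines = [
        "Dieting and leptin effects on the eating drive",
        "----------------------------------------------",
        f"mean drive outside dietary periods : "
        f"{report.deficit.mean_drive_outside:8.1f} cal/day "
        f"(SD {report.deficit.sd_drive_outside:.1f})",
        f"per-period mean deficits            : "
        + ", ".join(f"{m:.0f}" for m in report.period_means),
        f"overall mean deficit (pop. SD)      : {report.overall_mean:8.1f} "
        f"({report.overall_sd:.1f}) cal/day",
        f"one-sided t-test vs 0               : t = {report.t_stat:.3f}, "
        f"p = {report.p_value:.3f}",
        f"dieting effect                      : {report.pct_dieting:.1f}% "
        f"of the mean drive (prints as {round(report.pct_dieting)}%)",
        f"leptin effect (alpha*L_ref)         : {report.pct_leptin:.2f}% "
        f"(prints as {round(report.pct_leptin, 1)}%)",
        f"cross-correlation X(0)              : "
        f"{report.xcorr[np.flatnonzero(report.shifts == 0)[0]]:.6f}",
        f"smoothed X(s) peak at s             : "
        f"{report.shifts[int(np.argmax(np.convolve(report.xcorr, np.ones(3) / 3, mode='same')))]:g} months",
    ]
    return "\n".join(lines) + "\n"
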