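"""Forward integration of the intake model and its quasi-steady-state reduction.

The full system is stiff in a mild sense: leptin relaxes at gamma ~ 40/day
(a time scale of ~36 minutes) while the fat store drifts at eta ~ 1e-5 to
1e-4/day (months to years).  ``integrate_full`` therefore uses a
stiff-capable solver; ``integrate_qss`` integrates only the reduced scalar
calorie balance dC/dt = D(t) - eta*C - Q(t) and fills leptin in from the
quasi-steady state L = beta*C/gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigError, SimulationError
from .model import ModelParams, qss_leptin


@dataclass(frozen=True)
class Trajectory:
    """Time course of the system on a requested day grid."""

    t_day: np.ndarray     # days
    C: np.ndarray         # stored calories, cal
    L: np.ndarray         # plasma leptin, ng/ml
    W: np.ndarray         # weight, lb (C / (rho*delta))
    Q: np.ndarray         # expenditure, cal/day
    D: np.ndarray         # drive, cal/day

    def __post_init__(self) -> None:
        n = self.t_day.size
        for name in ("C", "L", "W", "Q", "D"):
            if getattr(self, name).size != n:
                raise ConfigError(f"trajectory field {name} has wrong length")
        if n >= 2 and not np.all(np.diff(self.t_day) > 0):
            raise ConfigError("trajectory time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_day": self.t_day, "C_cal": self.C, "L_ng_ml": self.L,
            "W_lb": self.W, "Q_cal_day": self.Q, "D_cal_day": self.D,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _check_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ConfigError("time grid must be a 1-d array with at least two points")
    if not np.all(np.diff(t) > 0):
        raise ConfigError("time grid must be strictly increasing")
    return t


def _finish(params: ModelParams, drive_fn, t: np.ndarray,
            C: np.ndarray, L: np.ndarray) -> Trajectory:
    W = params.calories_to_weight(C)
    Q = np.asarray(params.expenditure(t), dtype=float)
    D = np.asarray([drive_fn(ti) for ti in t], dtype=float)
    return Trajectory(t_day=t, C=C, L=L, W=np.asarray(W, dtype=float), Q=Q, D=D)


def integrate_full(params: ModelParams, drive_fn: Callable[[float], float],
                   C0: float, L0: float, t_grid: Sequence[float],
                   rtol: float = 1e-8) -> Trajectory:
    """Integrate the full two-state system (C, L) on ``t_grid`` (days)."""
    t = _check_grid(t_grid)
    for name in ("alpha", "beta", "gamma", "delta", "Q0"):
        if getattr(params, name) is None:
            raise ConfigError(f"integrate_full requires params.{name}")

    def rhs(ti, y):
        C, L = y
        dC = (drive_fn(ti) - params.alpha * L) - params.expenditure(ti)
        dL = params.beta * C - params.gamma * L
        return (dC, dL)

    sol = solve_ivp(rhs, (t[0], t[-1]), (float(C0), float(L0)), method="LSODA",
                    t_eval=t, rtol=rtol, atol=(1e-3, 1e-7))
    if not sol.success:
        raise SimulationError(
            f"full-system integration failed near t={sol.t[-1] if sol.t.size else t[0]:g} "
            f"day: {sol.message}"
        )
    return _finish(params, drive_fn, t, sol.y[0], sol.y[1])


def integrate_qss(params: ModelParams, drive_fn: Callable[[float], float],
                  C0: float, t_grid: Sequence[float], rtol: float = 1e-10,
                  switch_times: Optional[Sequence[float]] = None) -> Trajectory:
    """Integrate the reduced calorie balance; leptin filled in at QSS.

    ``switch_times`` lists days where ``drive_fn`` is discontinuous (e.g.
    month boundaries of a piecewise-constant drive); integration restarts
    there so step control never straddles a jump.
    """
    t = _check_grid(t_grid)
    for name in ("eta", "beta", "gamma", "delta", "Q0"):
        if getattr(params, name) is None:
            raise ConfigError(f"integrate_qss requires params.{name}")

    def rhs(ti, y):
        return (drive_fn(ti) - params.eta * y[0] - params.expenditure(ti),)

    breaks = [t[0], t[-1]]
    if switch_times is not None:
        breaks += [float(s) for s in switch_times if t[0] < s < t[-1]]
    breaks = sorted(set(breaks))

    C = np.empty(t.size)
    y0 = float(C0)
    filled = np.zeros(t.size, dtype=bool)
    for a, b in zip(breaks[:-1], breaks[1:]):
        inside = (t >= a) & (t <= b) & ~filled
        t_eval = np.unique(np.concatenate((t[inside], [a, b])))
        sol = solve_ivp(rhs, (a, b), (y0,), method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=1e-6)
        if not sol.success:
            raise SimulationError(
                f"QSS integration failed near t={sol.t[-1] if sol.t.size else a:g} "
                f"day: {sol.message}"
            )
        interp = np.interp(t[inside], sol.t, sol.y[0])
        C[inside] = interp
        filled[inside] = True
        y0 = float(sol.y[0][-1])
    L = np.asarray(qss_leptin(np.maximum(C, 0.0), params.beta, params.gamma))
    return _finish(params, drive_fn, t, C, L)


def fig2_preset_initial(params: ModelParams, W0_lb: float) -> tuple[float, float]:
    """Illustrative off-equilibrium start: leptin at zero, far from its QSS
    value, so a simulation exhibits the fast leptin transient before the slow
    drift of the fat store."""
    return float(params.weight_to_calories(W0_lb)), 0.0
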