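"""Numerical integration of compiled ODE systems.

Two integrators are provided:

- ``euler``: the fixed-step forward-Euler update ``y(t+h) = y(t) + h*dy``.
  Deterministic and bit-reproducible; the state may carry a trailing
  batch axis so several conditions integrate in one sweep.
- ``adaptive``: an explicit Runge-Kutta reference
  (:func:`scipy.integrate.solve_ivp`, RK45) at user tolerances.

States are concentrations/fold-changes, so transient negative values
(Euler overshoot) are clipped to zero; the number of clipped entries is
recorded on the trajectory for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .odes import ODESystem

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "sample",
    "trajectory_to_frame",
]


class IntegrationError(RuntimeError):
    """Raised when the derivative becomes non-finite during integration."""


@dataclass(frozen=True)
class SimulationSettings:
    """Time horizon and solver controls (hours)."""

    t0: float = 0.0
    t_end: float = 24.0
    h: float = 0.01
    method: str = "euler"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.t_end <= self.t0:
            raise ValueError(f"t_end ({self.t_end}) must exceed t0 ({self.t0})")
        if self.h <= 0:
            raise ValueError(f"step size h must be > 0, got {self.h}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.method not in ("euler", "adaptive"):
            raise ValueError(f"unknown method {self.method!r}")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t0) / self.h))
        n = max(n, 1)
        return self.t0 + (self.t_end - self.t0) * np.arange(n + 1) / n


@dataclass
class Trajectory:
    """Dense solution on the settings grid.

    ``states`` has shape ``(n_times, n_places)`` or
    ``(n_times, n_places, n_batch)`` for batched runs.
    """

    times: np.ndarray
    states: np.ndarray
    state_order: list[str]
    settings: SimulationSettings
    clip_count: int = 0

    def column(self, place: str) -> np.ndarray:
        return self.states[:, self.state_order.index(place)]

    def split(self) -> list["Trajectory"]:
        """Split a batched trajectory into per-condition trajectories."""
        if self.states.ndim == 2:
            return [self]
        return [
            Trajectory(
                times=self.times,
                states=self.states[:, :, b],
                state_order=self.state_order,
                settings=self.settings,
                clip_count=self.clip_count,
            )
            for b in range(self.states.shape[2])
        ]


def _check_finite(dy: np.ndarray, t: float, state_order: list[str]) -> None:
    if not np.all(np.isfinite(dy)):
        place_i = int(np.argwhere(~np.isfinite(dy))[0][0])
        raise IntegrationError(
            f"non-finite derivative at t={t:.6g} h for place {state_order[place_i]!r}"
        )


def integrate(
    odes: ODESystem,
    y0: np.ndarray,
    x: np.ndarray,
    inputs: Mapping[str, Callable[[float], float]] | None = None,
    settings: SimulationSettings = SimulationSettings(),
) -> Trajectory:
    """Integrate ``odes`` from ``y0`` under parameters ``x``.

    ``inputs`` clamps named places to time-dependent drives (evaluated
    at every step and at the stored grid times).  ``y0`` may be
    ``(n,)`` or ``(n, B)``; batched integration is only available in
    Euler mode for the adaptive solver loops over the batch.
    """
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    x = np.asarray(x, dtype=float)
    times = settings.grid()
    m = times.size
    clip_count = 0

    if settings.method == "euler":
        states = np.empty((m,) + y0.shape)
        y = y0.copy()
        h = times[1] - times[0]
        for k in range(m):
            t = times[k]
            if inputs:
                for pid, fn in inputs.items():
                    y[odes.index(pid)] = fn(t)
            states[k] = y
            if k == m - 1:
                break
            dy = odes.derivative(t, y, x)
            _check_finite(dy, t, odes.state_order)
            y = y + h * dy
            neg = y < 0
            if np.any(neg):
                clip_count += int(np.count_nonzero(neg))
                y[neg] = 0.0
        return Trajectory(times, states, list(odes.state_order), settings, clip_count)

    # adaptive: explicit RK via scipy, one condition at a time
    batched = y0.ndim == 2
    cols = y0.shape[1] if batched else 1
    out = np.empty((m, odes.n_states, cols))
    for b in range(cols):
        yb = y0[:, b].copy() if batched else y0.copy()

        def make_input(b_idx):
            if not inputs:
                return None
            def per_col(fn):
                def g(t):
                    v = np.asarray(fn(t), dtype=float)
                    return float(v if v.ndim == 0 else v[b_idx])
                return g
            return {pid: per_col(fn) for pid, fn in inputs.items()}

        local_inputs = make_input(b)

        def rhs(t, yv):
            dy = odes.derivative(t, yv, x, inputs=local_inputs)
            _check_finite(dy, t, odes.state_order)
            return dy

        if local_inputs:
            for pid, fn in local_inputs.items():
                yb[odes.index(pid)] = fn(times[0])
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            yb,
            method="RK45",
            t_eval=times,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
        )
        if not sol.success:  # pragma: no cover
            raise IntegrationError(f"adaptive solver failed: {sol.message}")
        ys = sol.y.T
        if local_inputs:
            for pid, fn in local_inputs.items():
                ys[:, odes.index(pid)] = [fn(t) for t in times]
        neg = ys < 0
        if np.any(neg):
            clip_count += int(np.count_nonzero(neg))
            ys = np.where(neg, 0.0, ys)
        out[:, :, b] = ys
    states = out if batched else out[:, :, 0]
    return Trajectory(times, states, list(odes.state_order), settings, clip_count)


def sample(traj: Trajectory, t: float | np.ndarray, place: str) -> float | np.ndarray:
    """Linearly interpolate the trajectory of ``place`` at time(s) ``t``.

    Exact at stored grid times; times outside the integrated range are a
    range error.
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = traj.times[0], traj.times[-1]
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise ValueError(f"sample time {t} outside [{lo}, {hi}] h")
    col = traj.column(place)
    if col.ndim != 1:
        raise ValueError("sample() expects an unbatched trajectory; use .split() first")
    out = np.interp(t_arr, traj.times, col)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def trajectory_to_frame(
    traj: Trajectory,
    dose_ug_ml: float | None = None,
    run_id: str = "run",
    places: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy export: columns time_h, place, value, dose_ug_ml, run_id."""
    places = places or traj.state_order
    frames = []
    for p in places:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": traj.times,
                    "place": p,
                    "value": traj.column(p),
                    "dose_ug_ml": dose_ug_ml,
                    "run_id": run_id,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
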