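"""Model calibration: penalized least squares solved with CMA-ES.

A measurement is a triple (place p, time t, dose s) with an observed
fold-change g.  Given a training set, the objective is

    f(x) = f0(x) + fu(x) + fl(x)

with the squared-error term f0 = sum |g - y(p, t, s; x)|^2 over training
measurements, and soft biological-bound penalties evaluated on a
simulation grid (all penalty times x observable places x doses):

    fu = lambda_u * sum max(y - u_p, 0)^2     (upper bounds u_p)
    fl = lambda_l * sum max(l_p - y, 0)^2     (lower bounds l_p)

subject to the positivity box x_lb < x < x_ub on the parameters.  The
box is enforced by projection repair inside the optimizer; optimization
runs in log10 parameter space so positivity is automatic and the search
spans the box's orders of magnitude evenly.  A failed simulation maps to
a large finite objective so the evolutionary ranking stays defined.

Held-out validation reports the mean percent relative deviation
``mean(100 * |y - g| / g)`` over the validation measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cmaes import minimize_cmaes
from .odes import ODESystem
from .simulate import SimulationSettings, Trajectory, integrate, sample

__all__ = [
    "Measurement",
    "ObjectiveSpec",
    "FitResult",
    "ODEModel",
    "squared_error",
    "penalty",
    "objective",
    "fit_cmaes",
    "validate",
    "default_bounds",
    "load_measurements",
    "save_measurements",
    "measurements_to_frame",
]

FAILURE_OBJECTIVE = 1e12

MEASUREMENT_COLUMNS = ["place", "time_h", "dose_ug_ml", "replicate", "value", "role"]


@dataclass(frozen=True)
class Measurement:
    """One observed fold-change for (place, time, dose)."""

    place: str
    time: float
    dose: float
    value: float
    role: str = "train"
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"measured fold-change must be >= 0, got {self.value}")
        if self.role not in ("train", "validation"):
            raise ValueError(f"role must be 'train' or 'validation', got {self.role!r}")

    @property
    def condition(self) -> tuple[str, float, float]:
        return (self.place, self.time, self.dose)


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "place": m.place,
                "time_h": m.time,
                "dose_ug_ml": m.dose,
                "replicate": m.replicate,
                "value": m.value,
                "role": m.role,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def _frame_to_measurements(df: pd.DataFrame) -> list[Measurement]:
    return [
        Measurement(
            place=str(r.place),
            time=float(r.time_h),
            dose=float(r.dose_ug_ml),
            replicate=int(r.replicate),
            value=float(r.value),
            role=str(r.role),
        )
        for r in df.itertuples()
    ]


def save_measurements(measurements: Iterable[Measurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def load_measurements(path: str | Path) -> list[Measurement]:
    return _frame_to_measurements(pd.read_csv(path))


def default_bounds(
    measurements: Sequence[Measurement],
    places: Sequence[str],
    lower: float = 0.0,
    factor: float = 10.0,
) -> dict[str, tuple[float, float]]:
    """Per-place (lower, upper) fold-change bounds: lower 0 and upper
    ``factor`` times the largest observed value for the place (largest
    overall for unmeasured places)."""
    values: dict[str, float] = {}
    for m in measurements:
        values[m.place] = max(values.get(m.place, 0.0), m.value)
    global_max = max(values.values(), default=1.0)
    return {p: (lower, factor * values.get(p, global_max)) for p in places}


@dataclass
class ObjectiveSpec:
    """Training set, penalty grid and box constraints."""

    train: list[Measurement]
    bounds: Mapping[str, tuple[float, float]]
    lambda_u: float = 1e3
    lambda_l: float = 1e3
    grid_times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 25.0, 1.0))
    grid_doses: tuple[float, ...] | None = None  # default: training doses
    xlb: float | np.ndarray = 1e-4
    xub: float | np.ndarray = 1e3

    def __post_init__(self) -> None:
        if self.lambda_u < 0 or self.lambda_l < 0:
            raise ValueError("penalty weights must be >= 0")
        for p, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {p!r}: need lower < upper, got ({lo}, {hi})")
        if not np.all(np.asarray(self.xlb) > 0):
            raise ValueError("xlb must be > 0")
        if not np.all(np.asarray(self.xub) > np.asarray(self.xlb)):
            raise ValueError("need xlb < xub")

    def penalty_doses(self) -> tuple[float, ...]:
        if self.grid_doses is not None:
            return tuple(self.grid_doses)
        return tuple(sorted({m.dose for m in self.train}))


@dataclass
class FitResult:
    """Best parameters and bookkeeping of one CMA-ES run."""

    x_star: dict[str, float]
    objective_trace: list[float]
    seed: int
    termination: str
    n_evals: int
    f_best: float
    validation_mean_deviation: float | None = None
    settings: dict | None = None

    @property
    def x_array(self) -> np.ndarray:
        return np.array(list(self.x_star.values()))

    def to_dict(self) -> dict:
        return {
            "x_star": self.x_star,
            "objective_trace": [float(v) for v in self.objective_trace],
            "seed": self.seed,
            "termination": self.termination,
            "n_evals": self.n_evals,
            "f_best": float(self.f_best),
            "validation_mean_deviation": self.validation_mean_deviation,
            "settings": self.settings,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        return cls(**json.loads(Path(path).read_text()))


class ODEModel:
    """Generic calibration wrapper around a compiled ODE system.

    Exposes the protocol the calibrator needs: ``free_names``,
    ``observables`` and ``simulate(x_free, doses, settings)``.  The
    free parameters are a (sub)set of the system's parameter names; any
    remaining parameters take fixed values.  Conditions (doses) share
    one trajectory unless an ``input_builder`` maps a dose to clamped
    input drives.
    """

    def __init__(
        self,
        odes: ODESystem,
        y0: np.ndarray,
        free_names: Sequence[str] | None = None,
        fixed: Mapping[str, float] | None = None,
        observables: Sequence[str] | None = None,
        input_builder=None,
    ):
        self.odes = odes
        self.y0 = np.asarray(y0, dtype=float)
        self.free_names = list(free_names or odes.parameter_names)
        self.fixed = dict(fixed or {})
        unknown = set(self.free_names + list(self.fixed)) - set(odes.parameter_names)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        self.observables = list(
            observables
            or [p.id for p in odes.net.places if not p.is_constant]
        )
        self.input_builder = input_builder

    def full_vector(self, x_free: np.ndarray) -> np.ndarray:
        values = dict(zip(self.free_names, np.asarray(x_free, dtype=float)))
        values.update(self.fixed)
        return np.array([values[n] for n in self.odes.parameter_names])

    def simulate(self, x_free, doses, settings: SimulationSettings) -> dict[float, Trajectory]:
        x = self.full_vector(x_free)
        out: dict[float, Trajectory] = {}
        shared: Trajectory | None = None
        for dose in np.atleast_1d(np.asarray(doses, dtype=float)):
            if self.input_builder is None:
                if shared is None:
                    shared = integrate(self.odes, self.y0, x, settings=settings)
                out[float(dose)] = shared
            else:
                out[float(dose)] = integrate(
                    self.odes, self.y0, x, inputs=self.input_builder(dose), settings=settings
                )
        return out


def _group_by_dose(measurements: Sequence[Measurement]) -> dict[float, list[Measurement]]:
    groups: dict[float, list[Measurement]] = {}
    for m in measurements:
        groups.setdefault(m.dose, []).append(m)
    return groups


def _residuals(
    trajectories: Mapping[float, Trajectory],
    measurements: Sequence[Measurement],
) -> np.ndarray:
    res = np.empty(len(measurements))
    for i, m in enumerate(measurements):
        traj = trajectories[m.dose]
        if m.place not in traj.state_order:
            raise KeyError(f"measurement refers to unknown place {m.place!r}")
        res[i] = m.value - sample(traj, m.time, m.place)
    return res


def squared_error(
    params,
    measurements: Sequence[Measurement],
    model,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """f0: sum of squared residuals over the given measurements.

    Simulates once per distinct dose.
    """
    doses = sorted({m.dose for m in measurements})
    trajs = model.simulate(params, doses, settings)
    return float(np.sum(_residuals(trajs, measurements) ** 2))


def _penalty_from_trajectories(
    trajectories: Mapping[float, Trajectory],
    model,
    spec: ObjectiveSpec,
) -> float:
    fu = fl = 0.0
    for dose in spec.penalty_doses():
        traj = trajectories[dose]
        for place in model.observables:
            if place not in spec.bounds:
                raise KeyError(f"no bounds defined for place {place!r}")
            lo, hi = spec.bounds[place]
            vals = np.interp(spec.grid_times, traj.times, traj.column(place))
            fu += float(np.sum(np.maximum(vals - hi, 0.0) ** 2))
            fl += float(np.sum(np.maximum(lo - vals, 0.0) ** 2))
    return spec.lambda_u * fu + spec.lambda_l * fl


def penalty(
    params,
    model,
    spec: ObjectiveSpec,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """fu + fl: positive-part squared bound violations on the penalty grid."""
    trajs = model.simulate(params, spec.penalty_doses(), settings)
    return _penalty_from_trajectories(trajs, model, spec)


def objective(
    params,
    model,
    spec: ObjectiveSpec,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """f0 + fu + fl, simulating each dose once."""
    doses = sorted({m.dose for m in spec.train} | set(spec.penalty_doses()))
    try:
        trajs = model.simulate(params, doses, settings)
        f0 = float(np.sum(_residuals(trajs, spec.train) ** 2))
        pen = _penalty_from_trajectories(trajs, model, spec)
    except (FloatingPointError, ArithmeticError, RuntimeError):
        return FAILURE_OBJECTIVE
    if not np.isfinite(f0 + pen):
        return FAILURE_OBJECTIVE
    return f0 + pen


def fit_cmaes(
    model,
    spec: ObjectiveSpec,
    x0: np.ndarray | None = None,
    sigma0: float = 0.3,
    seed: int = 0,
    max_evals: int = 20_000,
    popsize: int | None = None,
    settings: SimulationSettings = SimulationSettings(),
    ftarget: float | None = None,
    restarts: int = 0,
    **cma_options,
) -> FitResult:
    """Minimize the penalized objective with CMA-ES in log10 space.

    ``sigma0`` is the initial step size in log10 units (0.3 ~ a factor
    of two).  ``x0`` defaults to the geometric center of the box.
    ``restarts`` enables increasing-population restarts on stagnation.
    Fully reproducible for a given seed.
    """
    n = len(model.free_names)
    llo = np.log10(np.broadcast_to(np.asarray(spec.xlb, dtype=float), (n,)))
    lhi = np.log10(np.broadcast_to(np.asarray(spec.xub, dtype=float), (n,)))
    if x0 is None:
        # unit scale in the model's natural units (fold-changes per hour):
        # plausible kinetics sit within a couple of decades of 1
        u0 = np.clip(np.zeros(n), llo, lhi)
    else:
        x0 = np.asarray(x0, dtype=float)
        if np.any(x0 <= 0):
            raise ValueError("x0 must be strictly positive")
        u0 = np.clip(np.log10(x0), llo, lhi)

    def f(u: np.ndarray) -> float:
        return objective(10.0**u, model, spec, settings)

    res = minimize_cmaes(
        f,
        u0,
        sigma0,
        seed=seed,
        max_evals=max_evals,
        popsize=popsize,
        bounds=(llo, lhi),
        ftarget=ftarget,
        restarts=restarts,
        **cma_options,
    )
    x_star = 10.0**res.x_best
    return FitResult(
        x_star=dict(zip(model.free_names, map(float, x_star))),
        objective_trace=res.trace,
        seed=seed,
        termination=res.termination,
        n_evals=res.n_evals,
        f_best=res.f_best,
        settings={
            "sigma0": sigma0,
            "max_evals": max_evals,
            "popsize": popsize,
            "restarts": restarts,
            "t0": settings.t0,
            "t_end": settings.t_end,
            "h": settings.h,
            "method": settings.method,
        },
    )


def validate(
    fit,
    model,
    measurements: Sequence[Measurement],
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """Held-out mean deviation: ``mean(100 * |y - g| / g)`` in percent."""
    ms = list(measurements)
    if not ms:
        raise ValueError("validation set is empty")
    for m in ms:
        if m.value == 0:
            raise ValueError(
                f"validation measurement {m.condition} has value 0; "
                "relative deviation is undefined"
            )
    x = fit.x_array if isinstance(fit, FitResult) else np.asarray(fit, dtype=float)
    doses = sorted({m.dose for m in ms})
    trajs = model.simulate(x, doses, settings)
    devs = [
        100.0 * abs(sample(trajs[m.dose], m.time, m.place) - m.value) / m.value
        for m in ms
    ]
    return float(np.mean(devs))
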