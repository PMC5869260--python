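"""Synthetic measurement generation.

Stands in for the wet-lab study: noisy fold-change measurement sets are
generated from known ground-truth parameters under a declared
experimental design, so that calibration and held-out validation can be
exercised and quantified end to end.

The default noise model is mean-one multiplicative lognormal, the
natural choice for positive, ratio-scaled readouts (densitometry and
qPCR fold-changes): a value v becomes ``v * L`` with
``L ~ Lognormal(-s2/2, s2)``, ``s2 = ln(1 + sd^2)``, so ``E[vL] = v``
and ``SD[vL] = v * sd`` (sd is the coefficient of variation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibrate import Measurement
from .simulate import SimulationSettings, sample

__all__ = [
    "ExperimentalDesign",
    "NoiseModel",
    "reference_design",
    "generate",
    "split",
    "holdout_split",
    "write_manifest",
]


@dataclass(frozen=True)
class ExperimentalDesign:
    """A list of (place, time_h, dose_ug_ml) conditions with a replicate
    count per condition."""

    conditions: tuple[tuple[str, float, float], ...]
    replicates: int = 3

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design needs at least one condition")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for place, t, dose in self.conditions:
            if t <= 0:
                raise ValueError(f"condition ({place}, {t}, {dose}): time must be > 0")
            if dose < 0:
                raise ValueError(f"condition ({place}, {t}, {dose}): dose must be >= 0")

    @classmethod
    def factorial(
        cls,
        observables: Sequence[str],
        times: Sequence[float],
        doses: Sequence[float],
        replicates: int = 3,
    ) -> "ExperimentalDesign":
        return cls(
            conditions=tuple(
                (p, float(t), float(s)) for p in observables for t in times for s in doses
            ),
            replicates=replicates,
        )

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted({c[2] for c in self.conditions}))

    @property
    def observables(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c[0] for c in self.conditions))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: ``multiplicative_lognormal`` (mean-one, sd =
    coefficient of variation), ``additive_gaussian`` (sd in fold-change
    units, clipped at 0) or ``none``."""

    kind: str = "multiplicative_lognormal"
    sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.sd == 0:
            return values.copy()
        if self.kind == "multiplicative_lognormal":
            s2 = np.log1p(self.sd**2)
            factors = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=values.shape)
            return values * factors
        return np.clip(values + rng.normal(0.0, self.sd, size=values.shape), 0.0, None)


def reference_design(replicates: int = 3) -> ExperimentalDesign:
    """The composite design of the study this package emulates.

    Cleaved PARP (p4) has a full time course: doses {5, 10, 20} ug/ml
    by times {4, 8, 16, 24} h (12 conditions).  The five other
    observables (pERK1/2, cytochrome C, cleaved caspase 3, TNF-alpha
    mRNA, pRIP3) are each measured at the single reference condition
    10 ug/ml, 16 h.  Three replicates per condition.
    """
    conditions = [
        ("p4", float(t), float(s)) for s in (5.0, 10.0, 20.0) for t in (4.0, 8.0, 16.0, 24.0)
    ]
    conditions += [(p, 16.0, 10.0) for p in ("p1", "p2", "p3", "p8", "p9")]
    return ExperimentalDesign(conditions=tuple(conditions), replicates=replicates)


def generate(
    model,
    true_params,
    design: ExperimentalDesign,
    noise: NoiseModel = NoiseModel(kind="none", sd=0.0),
    settings: SimulationSettings = SimulationSettings(),
    role: str = "train",
) -> list[Measurement]:
    """Simulate the design's conditions once per dose, sample each
    (place, time) and apply per-replicate noise.

    Deterministic given ``noise.seed``.  Referencing a constant place is
    a design error.
    """
    constant = {p.id for p in model.odes.net.places if p.is_constant}
    for place, t, dose in design.conditions:
        if place in constant:
            raise ValueError(f"design measures constant place {place!r}")
        if place not in model.observables:
            raise ValueError(f"design measures unknown place {place!r}")
    rng = np.random.default_rng(noise.seed)
    trajs = model.simulate(true_params, list(design.doses), settings)
    out: list[Measurement] = []
    for place, t, dose in design.conditions:
        true_value = sample(trajs[dose], t, place)
        noisy = _clip_nonneg(noise.apply(np.full(design.replicates, true_value), rng))
        for r, v in enumerate(noisy):
            out.append(
                Measurement(place=place, time=t, dose=dose, value=float(v), role=role, replicate=r)
            )
    return out


def _clip_nonneg(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 0.0, None)


def split(
    measurements: Sequence[Measurement],
    holdout_fraction: float,
    seed: int = 0,
) -> tuple[list[Measurement], list[Measurement]]:
    """Partition by condition into (train, validation).

    Replicates of one condition never straddle the split.  Deterministic
    given ``seed``.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    conditions = sorted({m.condition for m in measurements})
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to split")
    rng = np.random.default_rng(seed)
    n_holdout = max(1, int(round(holdout_fraction * len(conditions))))
    if n_holdout >= len(conditions):
        raise ValueError("holdout would empty the training set")
    held = set(
        tuple(conditions[i]) for i in rng.choice(len(conditions), size=n_holdout, replace=False)
    )
    train = [
        Measurement(m.place, m.time, m.dose, m.value, "train", m.replicate)
        for m in measurements
        if m.condition not in held
    ]
    val = [
        Measurement(m.place, m.time, m.dose, m.value, "validation", m.replicate)
        for m in measurements
        if m.condition in held
    ]
    return train, val


def holdout_split(
    measurements: Sequence[Measurement],
    seed: int = 0,
) -> tuple[list[Measurement], list[Measurement]]:
    """Default split policy: hold out one full (time, dose) condition per
    observable, by seeded draw — only for observables measured under at
    least two conditions (single-condition observables stay in
    training)."""
    rng = np.random.default_rng(seed)
    by_place: dict[str, list[tuple[str, float, float]]] = {}
    for c in sorted({m.condition for m in measurements}):
        by_place.setdefault(c[0], []).append(c)
    held: set[tuple[str, float, float]] = set()
    for place in sorted(by_place):
        conds = by_place[place]
        if len(conds) >= 2:
            held.add(conds[int(rng.integers(len(conds)))])
    train = [
        Measurement(m.place, m.time, m.dose, m.value, "train", m.replicate)
        for m in measurements
        if m.condition not in held
    ]
    val = [
        Measurement(m.place, m.time, m.dose, m.value, "validation", m.replicate)
        for m in measurements
        if m.condition in held
    ]
    if not train:
        raise ValueError("holdout emptied the training set")
    return train, val


def write_manifest(
    path: str | Path,
    design: ExperimentalDesign,
    noise: NoiseModel,
    true_params=None,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Provenance record for a generated measurement set."""
    doc = {
        "design": {
            "conditions": [list(c) for c in design.conditions],
            "replicates": design.replicates,
        },
        "noise": {"kind": noise.kind, "sd": noise.sd, "seed": noise.seed},
        "seed": seed,
    }
    if true_params is not None:
        try:
            doc["true_parameters"] = true_params.as_dict()
        except AttributeError:
            doc["true_parameters"] = [float(v) for v in np.asarray(true_params).ravel()]
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))
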