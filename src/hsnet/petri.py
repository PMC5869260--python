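"""Continuous Petri net data model and kinetic rate laws.

A continuous Petri net is a bipartite graph of *places* (continuous
amounts, here dimensionless fold-changes relative to an unstimulated
control) and *transitions* (rate processes).  Standard arcs carry
stoichiometry: an arc place->transition consumes, transition->place
produces, each weighted.  *Read arcs* attach a place to a transition so
that it modulates the rate without being consumed or produced.

The net compiles to an ODE system (see :mod:`hsnet.odes`): the
derivative of each place is the weighted, signed sum of the fluxes of
its incident transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MASS_ACTION",
    "MM_COMPETITIVE_INHIBITION",
    "CONSTANT_SOURCE",
    "FIRST_ORDER",
    "RATE_LAW_KINDS",
    "NetStructureError",
    "RateLawError",
    "Place",
    "Arc",
    "KineticLaw",
    "Transition",
    "PetriNet",
    "build_net",
    "mass_action_rate",
    "mm_inhibition_rate",
]

MASS_ACTION = "mass_action"
MM_COMPETITIVE_INHIBITION = "mm_competitive_inhibition"
CONSTANT_SOURCE = "constant_source"
FIRST_ORDER = "first_order"

RATE_LAW_KINDS = frozenset(
    {MASS_ACTION, MM_COMPETITIVE_INHIBITION, CONSTANT_SOURCE, FIRST_ORDER}
)


class NetStructureError(ValueError):
    """Raised for structural defects: dangling arcs, duplicate ids,
    arcs violating bipartiteness."""


class RateLawError(ValueError):
    """Raised for invalid rate-law arguments or unresolvable parameter slots."""


@dataclass(frozen=True)
class Place:
    """A continuous place holding a non-negative amount.

    ``initial_value`` is a fold-change (baseline 1.0).  A constant place
    has its compiled derivative pinned to zero regardless of incident
    arcs; constant places model conserved precursor pools and externally
    clamped inputs.
    """

    id: str
    label: str = ""
    initial_value: float = 1.0
    is_constant: bool = False

    def __post_init__(self) -> None:
        if self.initial_value < 0:
            raise NetStructureError(
                f"place {self.id!r}: initial_value must be >= 0, got {self.initial_value}"
            )


@dataclass(frozen=True)
class Arc:
    """A weighted arc between a place and a transition (either direction).

    ``kind`` is ``"standard"`` (stoichiometric) or ``"read"`` (rate
    modifier only; never contributes to consumption/production).
    """

    source: str
    target: str
    weight: float = 1.0
    kind: str = "standard"

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "read"):
            raise NetStructureError(
                f"arc {self.source}->{self.target}: unknown kind {self.kind!r}"
            )
        if self.weight < 0:
            raise NetStructureError(
                f"arc {self.source}->{self.target}: weight must be >= 0, got {self.weight}"
            )


@dataclass(frozen=True)
class KineticLaw:
    """A rate law with named parameter slots resolving into the model's
    parameter vector.

    Slots by kind:

    - ``mass_action`` / ``first_order``: ``rate``
    - ``constant_source``: ``rate``
    - ``mm_competitive_inhibition``: ``vmax``, ``km``, ``ki``; the
      ``inhibitor`` field names the read-arc place acting as competitive
      inhibitor.
    """

    kind: str
    params: tuple[tuple[str, str], ...]  # (slot, parameter name), ordered
    inhibitor: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in RATE_LAW_KINDS:
            raise RateLawError(f"unknown rate-law kind {self.kind!r}")
        slots = [s for s, _ in self.params]
        if len(set(slots)) != len(slots):
            raise RateLawError(f"duplicate parameter slot in {slots}")
        required = (
            ("vmax", "km", "ki")
            if self.kind == MM_COMPETITIVE_INHIBITION
            else ("rate",)
        )
        for slot in required:
            if slot not in slots:
                raise RateLawError(f"law {self.kind!r} is missing slot {slot!r}")
        if self.kind == MM_COMPETITIVE_INHIBITION and self.inhibitor is None:
            raise RateLawError("mm_competitive_inhibition requires an inhibitor place")

    @classmethod
    def make(cls, kind: str, inhibitor: str | None = None, **slots: str) -> "KineticLaw":
        return cls(kind=kind, params=tuple(sorted(slots.items())), inhibitor=inhibitor)

    def slot(self, name: str) -> str:
        for s, p in self.params:
            if s == name:
                return p
        raise RateLawError(f"law {self.kind!r} has no slot {name!r}")


@dataclass
class Transition:
    """A rate process.  Substrates/products/modifiers are derived from the
    net's arcs by :func:`build_net` (lists of ``(place_id, weight)``)."""

    id: str
    law: KineticLaw
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    modifiers: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class PetriNet:
    places: list[Place]
    transitions: list[Transition]
    arcs: list[Arc]

    def place(self, place_id: str) -> Place:
        for p in self.places:
            if p.id == place_id:
                return p
        raise KeyError(place_id)

    def transition(self, transition_id: str) -> Transition:
        for t in self.transitions:
            if t.id == transition_id:
                return t
        raise KeyError(transition_id)

    @property
    def place_ids(self) -> list[str]:
        return [p.id for p in self.places]


def build_net(
    places: list[Place],
    transitions: list[Transition],
    arcs: list[Arc],
) -> PetriNet:
    """Validate structure and wire arc endpoints onto transitions.

    Checks: unique ids, at least one place, every arc endpoint exists,
    bipartiteness (no place-place or transition-transition arcs).
    Substrate/product/modifier lists on the transitions are rebuilt from
    the arcs.
    """
    if not places:
        raise NetStructureError("a net needs at least one place")
    pids = [p.id for p in places]
    tids = [t.id for t in transitions]
    for ids, what in ((pids, "place"), (tids, "transition")):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise NetStructureError(f"duplicate {what} id {i!r}")
            seen.add(i)
    overlap = set(pids) & set(tids)
    if overlap:
        raise NetStructureError(f"ids used for both a place and a transition: {sorted(overlap)}")

    pset, tset = set(pids), set(tids)
    tmap = {t.id: t for t in transitions}
    for t in transitions:
        t.substrates, t.products, t.modifiers = [], [], []
    for arc in arcs:
        s_is_p, t_is_p = arc.source in pset, arc.target in pset
        s_is_t, t_is_t = arc.source in tset, arc.target in tset
        if not (s_is_p or s_is_t):
            raise NetStructureError(f"arc {arc.source}->{arc.target}: unknown source {arc.source!r}")
        if not (t_is_p or t_is_t):
            raise NetStructureError(f"arc {arc.source}->{arc.target}: unknown target {arc.target!r}")
        if s_is_p and t_is_p:
            raise NetStructureError(
                f"arc {arc.source}->{arc.target} connects two places (net must be bipartite)"
            )
        if s_is_t and t_is_t:
            raise NetStructureError(
                f"arc {arc.source}->{arc.target} connects two transitions (net must be bipartite)"
            )
        if s_is_p:  # place -> transition
            tr = tmap[arc.target]
            if arc.kind == "read":
                tr.modifiers.append((arc.source, arc.weight))
            else:
                tr.substrates.append((arc.source, arc.weight))
        else:  # transition -> place
            if arc.kind == "read":
                raise NetStructureError(
                    f"arc {arc.source}->{arc.target}: read arcs must point from a place to a transition"
                )
            tmap[arc.source].products.append((arc.target, arc.weight))
    return PetriNet(places=list(places), transitions=list(transitions), arcs=list(arcs))


def mass_action_rate(rate_constant, substrate_values=(), weights=None):
    """Mass-action flux ``k * prod_i y_i**d_i`` (fold-change per hour).

    An empty substrate set yields the bare rate constant (a source
    transition).  Accepts scalars or numpy arrays for the substrate
    values.
    """
    if np.any(np.asarray(rate_constant) <= 0):
        raise RateLawError(f"rate constant must be > 0, got {rate_constant}")
    values = [np.asarray(v, dtype=float) for v in substrate_values]
    if weights is None:
        weights = [1.0] * len(values)
    if len(weights) != len(values):
        raise RateLawError("weights and substrate_values lengths differ")
    flux = np.asarray(rate_constant, dtype=float)
    for v, d in zip(values, weights):
        if np.any(v < 0):
            raise RateLawError(f"negative substrate value {v}")
        flux = flux * v**d
    return flux


def mm_inhibition_rate(vmax, km, ki, substrate, inhibitor=0.0):
    """Michaelis-Menten flux with competitive inhibition:
    ``Vmax * S / (S + Km * (1 + I/Ki))``.

    The inhibitor raises the apparent Km; at ``I=0`` this is plain
    Michaelis-Menten, and the flux saturates at ``Vmax`` for large S.
    """
    if np.any(np.asarray(vmax) <= 0):
        raise RateLawError(f"Vmax must be > 0, got {vmax}")
    if np.any(np.asarray(km) <= 0):
        raise RateLawError(f"Km must be > 0, got {km}")
    if np.any(np.asarray(ki) <= 0):
        raise RateLawError(f"Ki must be > 0, got {ki}")
    S = np.asarray(substrate, dtype=float)
    I = np.asarray(inhibitor, dtype=float)
    if np.any(S < 0):
        raise RateLawError(f"negative substrate value {substrate}")
    if np.any(I < 0):
        raise RateLawError(f"negative inhibitor value {inhibitor}")
    return vmax * S / (S + km * (1.0 + I / ki))
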