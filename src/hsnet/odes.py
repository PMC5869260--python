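"""Compilation of a continuous Petri net to an ODE system.

The derivative of place p is

    dy(p)/dt = sum_{tau in in(p)} d(tau, p) v(tau)
             - sum_{tau in out(p)} d(p, tau) v(tau)

where v(tau) is the transition's rate-law flux and d are the standard
arc weights.  Read arcs enter v(tau) but never the stoichiometric sums.
Constant places have their derivative pinned to zero.

The compiled derivative is fully vectorized: transition fluxes are
evaluated with grouped numpy operations and assembled through a dense
stoichiometric matrix, and the state may carry a trailing batch axis
``(n_places, n_batch)`` so that several experimental conditions (HS
doses) integrate in one pass.  Flux evaluation order is by transition id
so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .petri import (
    CONSTANT_SOURCE,
    FIRST_ORDER,
    MASS_ACTION,
    MM_COMPETITIVE_INHIBITION,
    PetriNet,
    RateLawError,
)

__all__ = ["ODESystem", "compile_odes", "CompilationError"]


class CompilationError(RateLawError):
    """A kinetic-law parameter slot did not resolve against the model's
    parameter names."""


@dataclass
class ODESystem:
    """A compiled ODE right-hand side with named states and parameters."""

    net: PetriNet
    state_order: list[str]
    parameter_names: list[str]
    constant_mask: np.ndarray  # bool, (n_places,)
    # power-law transitions (mass action / first order / constant source)
    _pl_rate_idx: np.ndarray = field(repr=False, default=None)
    _pl_sub_idx: np.ndarray = field(repr=False, default=None)  # (Tp, K) padded
    _pl_sub_w: np.ndarray = field(repr=False, default=None)
    _pl_flux_pos: np.ndarray = field(repr=False, default=None)
    # Michaelis-Menten competitive-inhibition transitions
    _mm_vmax_idx: np.ndarray = field(repr=False, default=None)
    _mm_km_idx: np.ndarray = field(repr=False, default=None)
    _mm_ki_idx: np.ndarray = field(repr=False, default=None)
    _mm_sub_idx: np.ndarray = field(repr=False, default=None)
    _mm_inh_idx: np.ndarray = field(repr=False, default=None)
    _mm_mod_idx: np.ndarray = field(repr=False, default=None)  # (Tm, K) padded
    _mm_mod_w: np.ndarray = field(repr=False, default=None)
    _mm_flux_pos: np.ndarray = field(repr=False, default=None)
    _stoich: np.ndarray = field(repr=False, default=None)  # (n_places, T)
    _n_transitions: int = 0

    @property
    def n_states(self) -> int:
        return len(self.state_order)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def index(self, place_id: str) -> int:
        return self.state_order.index(place_id)

    def parameter_index(self, name: str) -> int:
        return self.parameter_names.index(name)

    def fluxes(self, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Evaluate all transition fluxes (ordered by transition id).

        ``y`` may be ``(n,)`` or ``(n, B)``; the result has matching
        trailing shape.
        """
        y = np.asarray(y, dtype=float)
        batched = y.ndim == 2
        if not batched:
            y = y[:, None]
        x = np.asarray(x, dtype=float)
        B = y.shape[1]
        # pad with a virtual place fixed at 1 (index n) for unused slots
        yp = np.concatenate([y, np.ones((1, B))], axis=0)
        flux = np.empty((self._n_transitions, B))
        if self._pl_rate_idx.size:
            terms = yp[self._pl_sub_idx] ** self._pl_sub_w[:, :, None]
            flux[self._pl_flux_pos] = x[self._pl_rate_idx][:, None] * np.prod(terms, axis=1)
        if self._mm_vmax_idx.size:
            S = yp[self._mm_sub_idx]
            I = yp[self._mm_inh_idx]
            vmax = x[self._mm_vmax_idx][:, None]
            km = x[self._mm_km_idx][:, None]
            ki = x[self._mm_ki_idx][:, None]
            mod = np.prod(yp[self._mm_mod_idx] ** self._mm_mod_w[:, :, None], axis=1)
            flux[self._mm_flux_pos] = vmax * S / (S + km * (1.0 + I / ki)) * mod
        return flux if batched else flux[:, 0]

    def derivative(
        self,
        t: float,
        y: np.ndarray,
        x: np.ndarray,
        inputs: Mapping[str, Callable[[float], float]] | None = None,
    ) -> np.ndarray:
        """Evaluate dy/dt at time ``t``.

        ``inputs`` optionally clamps named places to time-dependent
        values before evaluating the fluxes (exogenous drives such as
        the HS exposure).  Constant places always get derivative 0.
        """
        y = np.asarray(y, dtype=float)
        batched = y.ndim == 2
        if inputs:
            y = y.copy()
            for pid, fn in inputs.items():
                y[self.index(pid)] = fn(t)
        flux = self.fluxes(y if batched else y, x)
        dy = self._stoich @ flux
        dy[self.constant_mask] = 0.0
        if inputs:
            for pid in inputs:
                dy[self.index(pid)] = 0.0
        return dy


def compile_odes(net: PetriNet, parameter_names: list[str]) -> ODESystem:
    """Compile ``net`` against an ordered parameter-name vector.

    Every kinetic-law slot must resolve to a name in
    ``parameter_names``; an unresolved slot raises
    :class:`CompilationError` naming the slot.
    """
    state_order = [p.id for p in net.places]
    pindex = {pid: i for i, pid in enumerate(state_order)}
    xindex = {name: i for i, name in enumerate(parameter_names)}
    n = len(state_order)
    PAD = n  # virtual always-one place

    def resolve(tr, slot: str) -> int:
        name = tr.law.slot(slot)
        if name not in xindex:
            raise CompilationError(
                f"transition {tr.id!r}: slot {slot!r} -> parameter {name!r} "
                "is not in the model's parameter names"
            )
        return xindex[name]

    order = sorted(net.transitions, key=lambda tr: tr.id)
    T = len(order)
    stoich = np.zeros((n, T))
    pl_rate, pl_subs, pl_pos = [], [], []
    mm_v, mm_km, mm_ki, mm_s, mm_i, mm_mods, mm_pos = [], [], [], [], [], [], []

    for j, tr in enumerate(order):
        for pid, w in tr.substrates:
            stoich[pindex[pid], j] -= w
        for pid, w in tr.products:
            stoich[pindex[pid], j] += w
        kind = tr.law.kind
        if kind in (MASS_ACTION, FIRST_ORDER, CONSTANT_SOURCE):
            contributors = list(tr.substrates) + list(tr.modifiers)
            if kind == CONSTANT_SOURCE and tr.substrates:
                raise CompilationError(
                    f"transition {tr.id!r}: constant_source cannot have substrates"
                )
            if kind == FIRST_ORDER and len(contributors) < 1:
                raise CompilationError(
                    f"transition {tr.id!r}: first_order needs a substrate"
                )
            pl_rate.append(resolve(tr, "rate"))
            pl_subs.append([(pindex[pid], w) for pid, w in contributors])
            pl_pos.append(j)
        elif kind == MM_COMPETITIVE_INHIBITION:
            if len(tr.substrates) != 1:
                raise CompilationError(
                    f"transition {tr.id!r}: mm_competitive_inhibition needs exactly "
                    f"one standard substrate, got {len(tr.substrates)}"
                )
            inh = tr.law.inhibitor
            mod_ids = [pid for pid, _ in tr.modifiers]
            if inh not in mod_ids:
                raise CompilationError(
                    f"transition {tr.id!r}: inhibitor {inh!r} must be attached by a read arc"
                )
            mm_v.append(resolve(tr, "vmax"))
            mm_km.append(resolve(tr, "km"))
            mm_ki.append(resolve(tr, "ki"))
            mm_s.append(pindex[tr.substrates[0][0]])
            mm_i.append(pindex[inh])
            mm_mods.append(
                [(pindex[pid], w) for pid, w in tr.modifiers if pid != inh]
            )
            mm_pos.append(j)
        else:  # pragma: no cover - guarded by KineticLaw
            raise CompilationError(f"transition {tr.id!r}: unknown law kind {kind!r}")

    def pad(groups: list[list[tuple[int, float]]]) -> tuple[np.ndarray, np.ndarray]:
        K = max((len(g) for g in groups), default=0)
        K = max(K, 1)
        idx = np.full((len(groups), K), PAD, dtype=np.intp)
        w = np.zeros((len(groups), K))
        for r, g in enumerate(groups):
            for c, (i, wt) in enumerate(g):
                idx[r, c], w[r, c] = i, wt
        return idx, w

    pl_sub_idx, pl_sub_w = pad(pl_subs)
    mm_mod_idx, mm_mod_w = pad(mm_mods)

    return ODESystem(
        net=net,
        state_order=state_order,
        parameter_names=list(parameter_names),
        constant_mask=np.array([p.is_constant for p in net.places]),
        _pl_rate_idx=np.asarray(pl_rate, dtype=np.intp),
        _pl_sub_idx=pl_sub_idx,
        _pl_sub_w=pl_sub_w,
        _pl_flux_pos=np.asarray(pl_pos, dtype=np.intp),
        _mm_vmax_idx=np.asarray(mm_v, dtype=np.intp),
        _mm_km_idx=np.asarray(mm_km, dtype=np.intp),
        _mm_ki_idx=np.asarray(mm_ki, dtype=np.intp),
        _mm_sub_idx=np.asarray(mm_s, dtype=np.intp),
        _mm_inh_idx=np.asarray(mm_i, dtype=np.intp),
        _mm_mod_idx=mm_mod_idx,
        _mm_mod_w=mm_mod_w,
        _mm_flux_pos=np.asarray(mm_pos, dtype=np.intp),
        _stoich=stoich,
        _n_transitions=T,
    )
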