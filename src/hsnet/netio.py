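"""YAML serialization of continuous Petri nets.

The on-disk form mirrors the object model: ``places`` (id, label,
initial, constant), ``transitions`` (id, law, params, inhibitor) and
``arcs`` (source, target, weight, kind).  Substrate/product/modifier
lists are derived from the arcs on load, so load -> save -> load is an
identity.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .petri import Arc, KineticLaw, PetriNet, Place, Transition, build_net

__all__ = ["net_to_dict", "net_from_dict", "save_net", "load_net"]


def net_to_dict(net: PetriNet) -> dict:
    return {
        "places": [
            {
                "id": p.id,
                "label": p.label,
                "initial": float(p.initial_value),
                "constant": bool(p.is_constant),
            }
            for p in net.places
        ],
        "transitions": [
            {
                "id": t.id,
                "law": t.law.kind,
                "params": {slot: name for slot, name in t.law.params},
                **({"inhibitor": t.law.inhibitor} if t.law.inhibitor else {}),
            }
            for t in net.transitions
        ],
        "arcs": [
            {
                "source": a.source,
                "target": a.target,
                "weight": float(a.weight),
                "kind": a.kind,
            }
            for a in net.arcs
        ],
    }


def net_from_dict(doc: dict) -> PetriNet:
    places = [
        Place(
            id=p["id"],
            label=p.get("label", ""),
            initial_value=float(p.get("initial", 1.0)),
            is_constant=bool(p.get("constant", False)),
        )
        for p in doc["places"]
    ]
    transitions = [
        Transition(
            id=t["id"],
            law=KineticLaw(
                kind=t["law"],
                params=tuple(sorted(t.get("params", {}).items())),
                inhibitor=t.get("inhibitor"),
            ),
        )
        for t in doc["transitions"]
    ]
    arcs = [
        Arc(
            source=a["source"],
            target=a["target"],
            weight=float(a.get("weight", 1.0)),
            kind=a.get("kind", "standard"),
        )
        for a in doc["arcs"]
    ]
    return build_net(places, transitions, arcs)


def save_net(net: PetriNet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(net_to_dict(net), sort_keys=False))


def load_net(path: str | Path) -> PetriNet:
    return net_from_dict(yaml.safe_load(Path(path).read_text()))
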