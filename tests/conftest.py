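import numpy as np
import pytest

from hsnet.pathway import HSPathwayModel, default_parameters
from hsnet.petri import (
    Arc,
    KineticLaw,
    Place,
    Transition,
    build_net,
)


@pytest.fixture(scope="session")
def model():
    return HSPathwayModel()


@pytest.fixture(scope="session")
def truth():
    return default_parameters()


@pytest.fixture()
def ab_net():
    """Minimal conversion A -> B with one mass-action rate k."""
    places = [Place("A", initial_value=3.0), Place("B", initial_value=0.0)]
    transitions = [Transition("t1", KineticLaw.make("mass_action", rate="k"))]
    arcs = [Arc("A", "t1"), Arc("t1", "B")]
    return build_net(places, transitions, arcs)


def random_mass_action_net(rng: np.random.Generator):
    """A random small net: <=4 places, <=3 mass-action transitions,
    integer arc weights <=2, occasional read arcs."""
    n_places = int(rng.integers(1, 5))
    n_trans = int(rng.integers(0, 4))
    places = [
        Place(f"p{i}", initial_value=float(rng.uniform(0.0, 3.0)))
        for i in range(n_places)
    ]
    transitions = []
    arcs = []
    for j in range(n_trans):
        tid = f"t{j}"
        transitions.append(Transition(tid, KineticLaw.make("mass_action", rate=f"k{j}")))
        n_sub = int(rng.integers(0, min(2, n_places) + 1))
        n_prod = int(rng.integers(0, min(2, n_places) + 1))
        for pid in rng.choice(n_places, size=n_sub, replace=False):
            arcs.append(Arc(f"p{pid}", tid, weight=float(rng.integers(1, 3))))
        for pid in rng.choice(n_places, size=n_prod, replace=False):
            arcs.append(Arc(tid, f"p{pid}", weight=float(rng.integers(1, 3))))
        if rng.random() < 0.3:
            pid = int(rng.integers(n_places))
            if not any(a.source == f"p{pid}" and a.target == tid for a in arcs):
                arcs.append(Arc(f"p{pid}", tid, weight=1.0, kind="read"))
    net = build_net(places, transitions, arcs)
    params = [f"k{j}" for j in range(n_trans)]
    x = rng.uniform(0.1, 2.0, size=n_trans)
    y = rng.uniform(0.0, 3.0, size=n_places)
    return net, params, x, y


def brute_force_derivative(net, params, x, y):
    """Independent term-by-term evaluation of the compiled sum: for each
    place, add d(tau,p)*v(tau) over incoming arcs and subtract
    d(p,tau)*v(tau) over outgoing standard arcs."""
    from hsnet.petri import mass_action_rate, mm_inhibition_rate

    yv = dict(zip([p.id for p in net.places], y))
    xv = dict(zip(params, x))

    def flux(tr):
        contribs = list(tr.substrates) + list(tr.modifiers)
        if tr.law.kind in ("mass_action", "first_order", "constant_source"):
            return mass_action_rate(
                xv[tr.law.slot("rate")],
                [yv[p] for p, _ in contribs],
                [w for _, w in contribs],
            )
        mods = [
            (p, w) for p, w in tr.modifiers if p != tr.law.inhibitor
        ]
        base = mm_inhibition_rate(
            xv[tr.law.slot("vmax")],
            xv[tr.law.slot("km")],
            xv[tr.law.slot("ki")],
            yv[tr.substrates[0][0]],
            yv[tr.law.inhibitor],
        )
        for p, w in mods:
            base = base * yv[p] ** w
        return base

    dy = {}
    for place in net.places:
        total = 0.0
        if not place.is_constant:
            for tr in net.transitions:
                v = flux(tr)
                for pid, w in tr.products:
                    if pid == place.id:
                        total += w * v
                for pid, w in tr.substrates:
                    if pid == place.id:
                        total -= w * v
        dy[place.id] = total
    return np.array([dy[p.id] for p in net.places])
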