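"""Net structure, rate laws and ODE compilation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsnet.odes import CompilationError, compile_odes
from hsnet.petri import (
    Arc,
    KineticLaw,
    NetStructureError,
    Place,
    RateLawError,
    Transition,
    build_net,
    mass_action_rate,
    mm_inhibition_rate,
)

from conftest import brute_force_derivative, random_mass_action_net


class TestBuildNet:
    def test_canonical_place_set(self, model):
        assert len(model.net.places) == 11
        assert model.net.place_ids == [f"p{i}" for i in range(11)]

    def test_single_place_no_transitions_has_zero_derivative(self):
        net = build_net([Place("A", initial_value=2.0)], [], [])
        odes = compile_odes(net, [])
        assert odes.derivative(0.0, np.array([2.0]), np.array([])) == pytest.approx(0.0)

    def test_place_place_arc_rejected(self):
        places = [Place("p1"), Place("p2")]
        with pytest.raises(NetStructureError, match="bipartite"):
            build_net(places, [], [Arc("p1", "p2")])

    def test_transition_transition_arc_rejected(self):
        places = [Place("A")]
        ts = [
            Transition("t1", KineticLaw.make("constant_source", rate="a")),
            Transition("t2", KineticLaw.make("constant_source", rate="a")),
        ]
        with pytest.raises(NetStructureError, match="bipartite"):
            build_net(places, ts, [Arc("t1", "t2")])

    def test_dangling_arc_names_the_arc(self):
        with pytest.raises(NetStructureError, match="ghost"):
            build_net([Place("A")], [], [Arc("A", "ghost")])

    def test_duplicate_id_names_the_id(self):
        with pytest.raises(NetStructureError, match="A"):
            build_net([Place("A"), Place("A")], [], [])

    def test_read_arc_must_enter_a_transition(self):
        places = [Place("A")]
        ts = [Transition("t1", KineticLaw.make("constant_source", rate="a"))]
        with pytest.raises(NetStructureError, match="read"):
            build_net(places, ts, [Arc("t1", "A", kind="read")])

    def test_negative_initial_value_rejected(self):
        with pytest.raises(NetStructureError):
            Place("A", initial_value=-0.5)


class TestRateLaws:
    @pytest.mark.parametrize(
        "k, values, weights, expected",
        [
            (2.0, [3.0], [1.0], 6.0),
            (5.0, [], None, 5.0),
            (1.0, [2.0], [2.0], 4.0),
            (0.5, [2.0, 3.0], [1.0, 1.0], 3.0),
        ],
    )
    def test_mass_action_values(self, k, values, weights, expected):
        assert mass_action_rate(k, values, weights) == pytest.approx(expected)

    def test_mass_action_rejects_negative_substrate(self):
        with pytest.raises(RateLawError):
            mass_action_rate(1.0, [-0.1], [1.0])

    def test_mm_reduces_to_michaelis_menten_without_inhibitor(self):
        for s in (0.1, 1.0, 7.3):
            assert mm_inhibition_rate(2.0, 0.7, 5.0, s, 0.0) == pytest.approx(
                2.0 * s / (s + 0.7)
            )

    def test_mm_unit_example(self):
        assert mm_inhibition_rate(1.0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0 / 3.0)

    def test_mm_saturates_at_vmax(self):
        assert mm_inhibition_rate(3.0, 2.0, 1.0, 1e6, 4.0) == pytest.approx(3.0, abs=1e-4)

    @pytest.mark.parametrize("km, ki", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_mm_rejects_nonpositive_constants(self, km, ki):
        with pytest.raises(RateLawError):
            mm_inhibition_rate(1.0, km, ki, 1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        k=st.floats(0.01, 10.0),
        y=st.floats(0.0, 5.0),
        w=st.floats(0.1, 3.0),
    )
    def test_mass_action_is_linear_in_the_rate_constant(self, k, y, w):
        assert mass_action_rate(2 * k, [y], [w]) == pytest.approx(
            2 * mass_action_rate(k, [y], [w])
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        vmax=st.floats(0.01, 10.0),
        km=st.floats(0.01, 10.0),
        ki=st.floats(0.01, 10.0),
        s=st.floats(0.0, 50.0),
        i=st.floats(0.0, 50.0),
    )
    def test_mm_flux_bounded_by_vmax_and_inhibitor_free_flux(self, vmax, km, ki, s, i):
        flux = mm_inhibition_rate(vmax, km, ki, s, i)
        assert 0.0 <= flux <= vmax + 1e-12
        assert flux <= mm_inhibition_rate(vmax, km, ki, s, 0.0) + 1e-12

    def test_inhibitor_monotonically_reduces_flux(self):
        fluxes = [mm_inhibition_rate(1.0, 1.0, 2.0, 1.5, i) for i in (0.0, 0.5, 1.0, 4.0)]
        assert all(a > b for a, b in zip(fluxes, fluxes[1:]))


class TestCompile:
    def test_single_reaction(self, ab_net):
        odes = compile_odes(ab_net, ["k"])
        dy = odes.derivative(0.0, np.array([3.0, 0.0]), np.array([0.5]))
        assert dy == pytest.approx([-1.5, 1.5])

    def test_weighted_reaction(self):
        places = [Place("A", initial_value=2.0), Place("B", initial_value=0.0)]
        ts = [Transition("t1", KineticLaw.make("mass_action", rate="k"))]
        arcs = [Arc("A", "t1", weight=2.0), Arc("t1", "B", weight=1.0)]
        odes = compile_odes(build_net(places, ts, arcs), ["k"])
        dy = odes.derivative(0.0, np.array([2.0, 0.0]), np.array([1.0]))
        # flux = 1 * 2^2 = 4; A loses 2 per firing, B gains 1
        assert dy == pytest.approx([-8.0, 4.0])

    def test_unresolved_slot_named(self, ab_net):
        with pytest.raises(CompilationError, match="rate.*k"):
            compile_odes(ab_net, ["other"])

    def test_constant_place_pinned(self):
        places = [Place("A", initial_value=1.0, is_constant=True), Place("B")]
        ts = [Transition("t1", KineticLaw.make("mass_action", rate="k"))]
        arcs = [Arc("A", "t1"), Arc("t1", "B")]
        odes = compile_odes(build_net(places, ts, arcs), ["k"])
        dy = odes.derivative(0.0, np.array([1.0, 1.0]), np.array([2.0]))
        assert dy[0] == 0.0
        assert dy[1] == pytest.approx(2.0)

    def test_oracle_equivalence_on_random_nets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            net, params, x, y = random_mass_action_net(rng)
            odes = compile_odes(net, params)
            compiled = odes.derivative(0.0, y, x)
            brute = brute_force_derivative(net, params, x, y)
            assert np.max(np.abs(compiled - brute)) < 1e-12

    def test_batched_matches_columnwise(self):
        rng = np.random.default_rng(3)
        net, params, x, _ = random_mass_action_net(rng)
        while not net.transitions:
            net, params, x, _ = random_mass_action_net(rng)
        odes = compile_odes(net, params)
        Y = rng.uniform(0.0, 2.0, size=(len(net.places), 5))
        batched = odes.derivative(0.0, Y, x)
        for b in range(5):
            assert batched[:, b] == pytest.approx(odes.derivative(0.0, Y[:, b], x))

    def test_stoichiometric_conservation_closed_net(self):
        # closed cycle A -> B -> C -> A, unit weights: total mass conserved
        places = [Place(c, initial_value=v) for c, v in zip("ABC", (1.0, 2.0, 0.5))]
        ts = [
            Transition(f"t{i}", KineticLaw.make("mass_action", rate=f"k{i}"))
            for i in range(3)
        ]
        arcs = [
            Arc("A", "t0"), Arc("t0", "B"),
            Arc("B", "t1"), Arc("t1", "C"),
            Arc("C", "t2"), Arc("t2", "A"),
        ]
        odes = compile_odes(build_net(places, ts, arcs), ["k0", "k1", "k2"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0.0, 5.0, size=3)
            x = rng.uniform(0.1, 3.0, size=3)
            assert abs(odes.derivative(0.0, y, x).sum()) < 1e-12

    def test_read_arc_changes_rate_not_stoichiometry(self):
        places = [Place("A", initial_value=2.0), Place("B"), Place("M", initial_value=3.0)]
        ts = [Transition("t1", KineticLaw.make("mass_action", rate="k"))]
        arcs = [Arc("A", "t1"), Arc("t1", "B")]
        plain = compile_odes(build_net(places, list(ts), list(arcs)), ["k"])
        ts2 = [Transition("t1", KineticLaw.make("mass_action", rate="k"))]
        with_read = compile_odes(
            build_net(places, ts2, arcs + [Arc("M", "t1", kind="read")]), ["k"]
        )
        y = np.array([2.0, 0.0, 3.0])
        x = np.array([1.0])
        dy0, dy1 = plain.derivative(0.0, y, x), with_read.derivative(0.0, y, x)
        # modifier place M gets no stoichiometric term
        assert dy1[2] == 0.0
        # rate is scaled by M's value, stoichiometric pattern unchanged
        assert dy1[:2] == pytest.approx(3.0 * dy0[:2])
        assert (dy1[:2] != 0).tolist() == (dy0[:2] != 0).tolist()

    def test_no_flux_from_empty_substrates(self):
        # zero substrate => zero flux for mass-action and MM transitions
        assert mass_action_rate(2.0, [0.0], [1.0]) == 0.0
        assert mm_inhibition_rate(2.0, 1.0, 1.0, 0.0, 0.5) == 0.0


class TestSerialization:
    def test_round_trip_identity(self, model, tmp_path):
        from hsnet.netio import load_net, save_net

        path = tmp_path / "net.yaml"
        save_net(model.net, path)
        loaded = load_net(path)
        assert loaded == model.net
        save_net(loaded, tmp_path / "net2.yaml")
        assert (tmp_path / "net2.yaml").read_text() == path.read_text()

    def test_bundled_model_matches_builder(self, model):
        from importlib.resources import files

        from hsnet.netio import net_from_dict
        import yaml

        doc = yaml.safe_load((files("hsnet") / "data" / "hs_model.yaml").read_text())
        assert net_from_dict(doc) == model.net
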