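"""Fuzzy Petri-net execution: membership, firing, stepping, fixed points."""

import itertools

import pytest

from fuzzygrn.engine import (
    EngineParams,
    SystemState,
    differential_response,
    fuzzify,
    simulate,
    step,
    transition_firing_degree,
)
from fuzzygrn.model import (
    Entity,
    Network,
    RegulatoryState,
    Transition,
    TransitionInput,
    TransitionOutput,
    UnknownEntityError,
)
from fuzzygrn.synth import SynthConfig, generate_network


class TestFuzzify:
    def test_baseline_is_pure_neutral(self):
        m = fuzzify(0.5, 0.5)
        assert m.degree("neutral") == 1.0
        assert sum(m.terms.values()) == pytest.approx(1.0)

    def test_extreme_is_pure_up_strong(self):
        assert fuzzify(1.0, 0.5).degree("up_strong") == 1.0

    def test_extreme_low_is_pure_down_strong(self):
        assert fuzzify(0.0, 0.5).degree("down_strong") == 1.0

    def test_between_centers_splits_two_terms(self):
        # 0.6 lies between neutral (0.5) and up_weak (0.65)
        m = fuzzify(0.6, 0.5)
        nonzero = {t: d for t, d in m.terms.items() if d > 0}
        assert set(nonzero) == {"neutral", "up_weak"}
        assert nonzero["neutral"] == pytest.approx(1 / 3)
        assert nonzero["up_weak"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("level", [-0.1, 1.1])
    def test_out_of_range_rejected(self, level):
        with pytest.raises(ValueError):
            fuzzify(level, 0.5)

    @pytest.mark.parametrize("level", [0.0, 0.07, 0.2, 0.33, 0.5, 0.61, 0.8, 0.95, 1.0])
    def test_partition_of_unity(self, level):
        assert sum(fuzzify(level, 0.5).terms.values()) == pytest.approx(1.0)


def two_signal_transition():
    return Transition(
        id="T",
        process="p",
        inputs=(
            TransitionInput("s1", "signal", RegulatoryState("present")),
            TransitionInput("s2", "signal", RegulatoryState("present")),
        ),
        outputs=(TransitionOutput("g", "up", "strong", "activation"),),
    )


class TestFiringDegree:
    def test_all_inputs_satisfied_gives_one(self):
        state = SystemState({"s1": 1.0, "s2": 1.0})
        assert transition_firing_degree(two_signal_transition(), state) == 1.0

    def test_absent_required_signal_blocks(self):
        state = SystemState({"s1": 0.0, "s2": 1.0})
        assert transition_firing_degree(two_signal_transition(), state) == 0.0

    def test_min_rule(self):
        state = SystemState({"s1": 0.8, "s2": 0.3})
        assert transition_firing_degree(two_signal_transition(), state) == pytest.approx(0.3)

    def test_tf_requirement_uses_membership(self):
        tr = Transition(
            id="T",
            process="p",
            inputs=(TransitionInput("tf1", "tf", RegulatoryState("up", "strong")),),
            outputs=(TransitionOutput("g", "up", "weak", "activation"),),
        )
        assert transition_firing_degree(tr, SystemState({"tf1": 0.95})) == pytest.approx(1.0)
        assert transition_firing_degree(tr, SystemState({"tf1": 0.5})) == 0.0


def single_transition_network(magnitude="strong", direction="up"):
    entities = [
        Entity(id="s", name="s", etype="signal"),
        Entity(id="g", name="g", etype="gene"),
    ]
    tr = Transition(
        id="T",
        process="p",
        inputs=(TransitionInput("s", "signal", RegulatoryState("present")),),
        outputs=(
            TransitionOutput(
                "g", direction, magnitude,
                "activation" if direction == "up" else "inhibition",
            ),
        ),
    )
    return Network.from_lists(entities, [tr])


class TestStep:
    def test_no_transitions_leaves_state(self):
        net = Network.from_lists([Entity(id="g", name="g", etype="gene")], [])
        state = SystemState({"g": 0.7})
        assert step(net, state).levels == state.levels

    def test_single_strong_activation(self):
        net = single_transition_network("strong")
        new = step(net, SystemState({"s": 1.0}))
        assert new.level("g") == pytest.approx(0.95)

    def test_opposing_medium_transitions_cancel(self):
        entities = [
            Entity(id="s", name="s", etype="signal"),
            Entity(id="g", name="g", etype="gene"),
        ]
        up = Transition(
            id="T1", process="p",
            inputs=(TransitionInput("s", "signal", RegulatoryState("present")),),
            outputs=(TransitionOutput("g", "up", "medium", "activation"),),
        )
        down = Transition(
            id="T2", process="p",
            inputs=(TransitionInput("s", "signal", RegulatoryState("present")),),
            outputs=(TransitionOutput("g", "down", "medium", "inhibition"),),
        )
        net = Network.from_lists(entities, [up, down])
        assert step(net, SystemState({"s": 1.0})).level("g") == pytest.approx(0.5)

    def test_clamped_target_is_not_updated(self):
        net = single_transition_network("strong")
        new = step(net, SystemState({"s": 1.0, "g": 0.2}), clamped={"g"})
        assert new.level("g") == 0.2


class TestSimulatePck1:
    """Context-gating of the gluconeogenic PCK1 activation."""

    def test_glucose_context_makes_cat8_knockout_inert(self, pck1):
        res = simulate(
            pck1,
            context={"glucose": "present", "ethanol": "absent"},
            perturbations={"CAT8": "knockout"},
        )
        assert res.converged
        assert res.final.level("PCK1") == pytest.approx(0.5)

    def test_ethanol_context_raises_pck1(self, pck1):
        res = simulate(pck1, context={"glucose": "absent", "ethanol": "present"})
        assert res.converged
        assert res.final.level("PCK1") > 0.5
        assert res.final.level("CAT8") > 0.5

    def test_ethanol_context_with_cat8_knockout_still_partial(self, pck1):
        # SIP4 path remains, so PCK1 rises less than with CAT8 present
        full = simulate(pck1, {"glucose": "absent", "ethanol": "present"})
        ko = simulate(
            pck1, {"glucose": "absent", "ethanol": "present"}, {"CAT8": "knockout"}
        )
        assert 0.5 < ko.final.level("PCK1") <= full.final.level("PCK1")

    def test_no_enabled_transitions_converges_immediately(self):
        net = single_transition_network()
        res = simulate(net, context={"s": "absent"})
        assert res.converged and res.iterations == 1
        assert res.final.level("g") == pytest.approx(0.5)

    def test_unknown_context_entity_raises(self, pck1):
        with pytest.raises(UnknownEntityError):
            simulate(pck1, context={"xylose": "present"})


class TestDifferentialResponse:
    def test_pck1_glucose_to_ethanol_switch_is_strong_up(self, pck1):
        diff = differential_response(
            pck1,
            {"glucose": "present", "ethanol": "absent"},
            {"glucose": "absent", "ethanol": "present"},
        )
        assert diff["PCK1"] == ("up", "strong")

    def test_identical_contexts_give_empty_mapping(self, pck1):
        ctx = {"glucose": "present", "ethanol": "absent"}
        assert differential_response(pck1, ctx, dict(ctx)) == {}

    def test_inhibition_only_network_pushes_targets_down(self):
        net = single_transition_network("medium", direction="down")
        diff = differential_response(net, {"s": "absent"}, {"s": "present"})
        assert all(d == "down" for d, _ in diff.values())


class TestEngineInvariants:
    @pytest.mark.parametrize("seed", range(0, 200, 1))
    def test_levels_stay_in_unit_interval(self, seed):
        cfg = SynthConfig(
            n_tgs=4, n_tfs=3, n_signals=6, n_transitions=8, seed=seed,
            inputs_per_transition=(1, 3),
        )
        net = generate_network(cfg)
        context = {f"sig{i:03d}": ("present" if (seed + i) % 2 else "absent") for i in range(3)}
        res = simulate(net, context=context, max_iter=20)
        for state in res.trajectory:
            assert all(0.0 <= v <= 1.0 for v in state.levels.values())

    def test_determinism(self, pck1):
        a = simulate(pck1, {"glucose": "absent", "ethanol": "present"})
        b = simulate(pck1, {"glucose": "absent", "ethanol": "present"})
        assert [s.levels for s in a.trajectory] == [s.levels for s in b.trajectory]

    def test_context_neutrality_absent_gate_contributes_zero(self):
        """A transition whose required signal is absent adds exactly nothing,
        whatever the other inputs do."""
        entities = [
            Entity(id="gate", name="gate", etype="signal"),
            Entity(id="tf1", name="tf1", etype="tf"),
            Entity(id="g", name="g", etype="gene"),
        ]
        tr = Transition(
            id="T", process="p",
            inputs=(
                TransitionInput("gate", "signal", RegulatoryState("present")),
                TransitionInput("tf1", "tf", RegulatoryState("up", "na")),
            ),
            outputs=(TransitionOutput("g", "up", "strong", "activation"),),
        )
        net = Network.from_lists(entities, [tr])
        for pert in ({}, {"tf1": "overexpression"}):
            res = simulate(net, {"gate": "absent"}, pert)
            assert res.final.level("g") == pytest.approx(0.5)

    def test_monotonicity_on_activation_only_network(self):
        """Raising a clamped activator level never lowers any fixed point."""
        entities = [
            Entity(id="tfA", name="tfA", etype="tf"),
            Entity(id="tfB", name="tfB", etype="tf"),
            Entity(id="g1", name="g1", etype="gene"),
            Entity(id="g2", name="g2", etype="gene"),
        ]
        t1 = Transition(
            id="T1", process="p",
            inputs=(TransitionInput("tfA", "tf", RegulatoryState("up", "na")),),
            outputs=(TransitionOutput("tfB", "up", "medium", "activation"),),
        )
        t2 = Transition(
            id="T2", process="p",
            inputs=(TransitionInput("tfB", "tf", RegulatoryState("up", "na")),),
            outputs=(TransitionOutput("g1", "up", "strong", "activation"),),
        )
        t3 = Transition(
            id="T3", process="p",
            inputs=(TransitionInput("tfA", "tf", RegulatoryState("up", "na")),),
            outputs=(TransitionOutput("g2", "up", "weak", "activation"),),
        )
        net = Network.from_lists(entities, [t1, t2, t3])

        def fixed_point(level):
            params = EngineParams()
            state = SystemState({"tfA": level})
            for _ in range(50):
                state = step(net, state, params, clamped={"tfA"})
            return state

        prev = None
        for level in [0.0, 0.25, 0.5, 0.6, 0.75, 0.9, 1.0]:
            fp = fixed_point(level)
            if prev is not None:
                for eid in ("tfB", "g1", "g2"):
                    assert fp.level(eid) >= prev.level(eid) - 1e-12
            prev = fp

    def test_boolean_limit_matches_exhaustive_oracle(self):
        """With all inputs clamped to {0,1} and all magnitudes strong, the
        fixed point agrees with plain Boolean rule evaluation."""
        entities = [
            Entity(id="s1", name="s1", etype="signal"),
            Entity(id="s2", name="s2", etype="signal"),
            Entity(id="tf1", name="tf1", etype="tf"),
            Entity(id="tf2", name="tf2", etype="tf"),
            Entity(id="g1", name="g1", etype="gene"),
            Entity(id="g2", name="g2", etype="gene"),
        ]
        t1 = Transition(
            id="T1", process="p",
            inputs=(
                TransitionInput("s1", "signal", RegulatoryState("present")),
                TransitionInput("tf1", "tf", RegulatoryState("up", "strong")),
            ),
            outputs=(TransitionOutput("g1", "up", "strong", "activation"),),
        )
        t2 = Transition(
            id="T2", process="p",
            inputs=(
                TransitionInput("s2", "signal", RegulatoryState("absent")),
                TransitionInput("tf2", "tf", RegulatoryState("down", "strong")),
            ),
            outputs=(TransitionOutput("g2", "down", "strong", "inhibition"),),
        )
        net = Network.from_lists(entities, [t1, t2])

        def boolean_eval(assign):
            fired1 = assign["s1"] == 1 and assign["tf1"] == 1
            fired2 = assign["s2"] == 0 and assign["tf2"] == 0
            return {"g1": 1 if fired1 else None, "g2": 0 if fired2 else None}

        inputs = ["s1", "s2", "tf1", "tf2"]
        for bits in itertools.product([0, 1], repeat=4):
            assign = dict(zip(inputs, bits))
            context = {
                "s1": "present" if assign["s1"] else "absent",
                "s2": "present" if assign["s2"] else "absent",
            }
            pert = {
                "tf1": "overexpression" if assign["tf1"] else "knockout",
                "tf2": "overexpression" if assign["tf2"] else "knockout",
            }
            res = simulate(net, context, pert)
            expected = boolean_eval(assign)
            for g, want in expected.items():
                lvl = res.final.level(g)
                if want is None:
                    assert lvl == pytest.approx(0.5)
                elif want == 1:
                    assert lvl > 0.5
                else:
                    assert lvl < 0.5
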