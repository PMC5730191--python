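"""Network construction, state handling, and update semantics."""

import numpy as np
import pytest

import saspnet as sn
from saspnet.network import NetworkError
from tests.conftest import corpus_spec


@pytest.fixture
def negation_net():
    return sn.BooleanNetwork([("X", "!X")])


class TestConstruction:
    def test_duplicate_node_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            sn.BooleanNetwork([("A", "B"), ("A", "!B"), ("B", "A")])

    def test_undefined_reference_rejected(self):
        with pytest.raises(NetworkError, match="X"):
            sn.BooleanNetwork([("Y", "X")])

    def test_inputs_are_self_identity_nodes(self):
        net = sn.BooleanNetwork([("S", "S"), ("A", "S & !A"), ("B", "B | A")])
        assert net.inputs == ("S",)  # B's rule is not the bare identity

    def test_state_layout_follows_declaration_order(self):
        net = sn.BooleanNetwork([("B", "A"), ("A", "B")])
        state = net.state({"B": 1})
        assert state.bits == (1, 0)
        assert state.to_int() == 1
        assert net.state_from_int(2)["A"] == 1

    def test_state_validation(self):
        net = sn.BooleanNetwork([("A", "A")])
        with pytest.raises(NetworkError):
            net.state({"nope": 1})
        with pytest.raises(NetworkError):
            sn.State(("A",), (2,))


class TestSynchronousStep:
    def test_sasp_step_from_dna_damage(self, sasp_model):
        net = sasp_model.network
        after = sn.synchronous_step(net, sasp_model.condition_state("dna_damage"))
        active = {n for n in net.nodes if after[n]}
        assert active == {"DNAD", "ATM", "ATR", "NEMO", "p16INK4", "RB", "CDK4"}

    def test_sasp_step_from_all_zero(self, sasp_model):
        net = sasp_model.network
        after = sn.synchronous_step(net, sasp_model.condition_state("baseline"))
        assert {n for n in net.nodes if after[n]} == {"RB", "CDK4"}

    def test_fixed_point_maps_to_itself(self, sasp_model):
        net = sasp_model.network
        cycle_fixed = net.state({"CDK2": 1, "CDK4": 1, "pRB": 1, "E2F": 1})
        assert sn.synchronous_step(net, cycle_fixed) == cycle_fixed

    def test_compiled_step_matches_interpreted(self, random_corpus):
        for net in random_corpus[:20]:
            step = net.compiled_step()
            for packed in range(0, 1 << len(net), 7):
                state = net.state_from_int(packed)
                assert net.state_from_int(step(packed)) == sn.synchronous_step(net, state)


class TestAsynchronousStep:
    def test_single_node_update(self, sasp_model):
        net = sasp_model.network
        state = net.state({"IKK": 1})
        after = sn.asynchronous_step(net, state, "NFkB")
        assert after["NFkB"] == 1
        assert after.replace(NFkB=0) == state

    def test_input_node_is_inert(self, sasp_model):
        state = sasp_model.condition_state("dna_damage")
        assert sn.asynchronous_step(sasp_model.network, state, "DNAD") == state

    def test_unknown_node_rejected(self, sasp_model):
        with pytest.raises(NetworkError):
            sn.asynchronous_step(sasp_model.network, sasp_model.condition_state("baseline"), "XYZ")

    def test_agrees_with_synchronous_bit_and_hamming_locality(self, random_corpus):
        rng = np.random.default_rng(11)
        for net in random_corpus[:30]:
            packed = int(rng.integers(0, 1 << len(net)))
            state = net.state_from_int(packed)
            node = net.nodes[int(rng.integers(0, len(net)))]
            asynchronous = sn.asynchronous_step(net, state, node)
            synchronous = sn.synchronous_step(net, state)
            assert asynchronous[node] == synchronous[node]
            hamming = sum(a != b for a, b in zip(asynchronous.bits, state.bits))
            assert hamming <= 1


class TestSimulate:
    def test_negation_oscillator(self, negation_net):
        traj = sn.simulate(negation_net, negation_net.state(), max_steps=10)
        assert [s.bits for s in traj] == [(0,), (1,), (0,)]
        assert traj.recurrence_time == 3
        assert traj.first_occurrence == 1

    def test_determinism(self, sasp_model):
        initial = sasp_model.condition_state("dna_damage")
        a = sn.simulate(sasp_model.network, initial)
        b = sn.simulate(sasp_model.network, initial)
        assert [s.bits for s in a] == [s.bits for s in b]

    def test_recurrence_within_state_space_bound(self):
        for i in range(0, 60, 3):
            net = sn.generate_random_network(corpus_spec(i))
            traj = sn.simulate(net, net.state(), max_steps=(1 << len(net)) + 1)
            assert traj.first_occurrence is not None
            assert len(traj) <= (1 << len(net)) + 1

    def test_time_indexing_is_one_based(self, sasp_model):
        traj = sn.simulate(sasp_model.network, sasp_model.condition_state("dna_damage"))
        assert traj.state_at(1) == sasp_model.condition_state("dna_damage")
        with pytest.raises(IndexError):
            traj.state_at(0)


class TestFirstActivation:
    def test_no_damage_cell_cycle_entry(self, sasp_model):
        traj = sn.simulate(sasp_model.network, sasp_model.condition_state("baseline"))
        assert sn.first_activation_time(traj, "CDK4") == 2
        assert sn.first_activation_time(traj, "IL6") is None

    def test_input_active_at_initial_time(self, sasp_model):
        traj = sn.simulate(sasp_model.network, sasp_model.condition_state("dna_damage"))
        assert sn.first_activation_time(traj, "DNAD") == 1

    def test_unknown_node_rejected(self, sasp_model):
        traj = sn.simulate(sasp_model.network, sasp_model.condition_state("baseline"), 3)
        with pytest.raises(NetworkError):
            sn.first_activation_time(traj, "nope")
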