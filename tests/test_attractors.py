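"""Attractor detection, reduction machinery, and scheme equivalence."""

import pytest

import saspnet as sn
from saspnet.attractors import Attractor, ResourceCapExceeded
from saspnet.expr import equivalent
from saspnet.network import NetworkError


@pytest.fixture
def two_node_copy_net():
    return sn.BooleanNetwork([("A", "B"), ("B", "A")])


class TestAttractorFromState:
    def test_baseline_point_attractor(self, sasp_model):
        net = sasp_model.network
        att = sn.attractor_from_state(net, sasp_model.condition_state("baseline"))
        assert att.is_point
        expected = net.state({"CDK2": 1, "CDK4": 1, "pRB": 1, "E2F": 1})
        assert att.states[0] == expected

    def test_two_cycle(self, two_node_copy_net):
        att = sn.attractor_from_state(two_node_copy_net, two_node_copy_net.state({"B": 1}))
        assert len(att) == 2
        assert {s.bits for s in att.states} == {(0, 1), (1, 0)}

    def test_fixed_point_gives_singleton(self, two_node_copy_net):
        att = sn.attractor_from_state(two_node_copy_net, two_node_copy_net.state({"A": 1, "B": 1}))
        assert att.is_point and att.states[0].bits == (1, 1)

    def test_canonical_form_is_phase_invariant(self, two_node_copy_net):
        states = [two_node_copy_net.state({"A": 1}), two_node_copy_net.state({"B": 1})]
        assert Attractor(tuple(states)) == Attractor(tuple(reversed(states)))


class TestReduceFixedInputs:
    def test_sasp_no_damage_freezes_ddr_axis(self, sasp_model):
        reduced = sn.reduce_fixed_inputs(
            sasp_model.network, {"DNAD": 0, "Hypoxia": 0}
        )
        for node in ("ATM", "ATR", "CHK1", "CHK2", "NEMO", "HIF1"):
            assert reduced.constants[node] == 0

    def test_constants_reproduce_residual_rules(self, sasp_model):
        net = sasp_model.network
        reduced = sn.reduce_fixed_inputs(net, {"DNAD": 1, "Hypoxia": 0})
        for name in reduced.residual_nodes:
            substituted = net.rule(name).substitute(reduced.constants)
            assert equivalent(substituted, dict(reduced.residual_rules)[name])

    def test_dna_damage_fully_determines_the_network(self, sasp_model):
        reduced = sn.reduce_fixed_inputs(sasp_model.network, {"DNAD": 1, "Hypoxia": 0})
        assert reduced.residual_rules == ()
        assert reduced.network is None
        assert reduced.constants["NFkB"] == 1 and reduced.constants["IkB"] == 0

    def test_no_inputs_is_identity_reduction(self, two_node_copy_net):
        reduced = sn.reduce_fixed_inputs(two_node_copy_net, {})
        assert reduced.residual_nodes == ("A", "B")
        assert reduced.constants == {}

    def test_non_input_assignment_rejected(self, sasp_model):
        with pytest.raises(NetworkError, match="perturbation"):
            sn.reduce_fixed_inputs(sasp_model.network, {"NFkB": 0})


class TestExhaustive:
    def test_negation_oscillator(self):
        net = sn.BooleanNetwork([("X", "!X")])
        atts = sn.exhaustive_attractors(net)
        assert len(atts) == 1
        assert len(atts[0]) == 2 and atts[0].basin_size == 2

    def test_copy_pair_has_three_attractors(self, two_node_copy_net):
        atts = sn.exhaustive_attractors(two_node_copy_net)
        assert len(atts) == 3
        assert sorted(len(a) for a in atts) == [1, 1, 2]
        assert sum(a.basin_size for a in atts) == 4

    def test_basin_partition_on_random_networks(self, random_corpus):
        for net in random_corpus[:40]:
            atts = sn.exhaustive_attractors(net)
            assert sum(a.basin_size for a in atts) == 1 << len(net)

    def test_reduction_matches_brute_force_subset(
        self, random_corpus, corpus_brute_attractors
    ):
        # Full 200-network comparison lives in the acceptance suite.
        for net, brute in zip(random_corpus[:50], corpus_brute_attractors[:50]):
            reduced = sn.exhaustive_attractors(net, strategy="reduction", basins=True)
            assert set(reduced) == set(brute)
            expected = {a: a.basin_size for a in brute}
            assert all(expected[a] == a.basin_size for a in reduced)

    def test_branch_and_reduce_agrees_with_brute_force(self):
        # Self-maintaining S forces the absorbing-node branch when the
        # component cap is tiny; attractor sets must still agree exactly.
        net = sn.BooleanNetwork(
            [
                ("S", "S | A"),
                ("A", "B & !S"),
                ("B", "C | S"),
                ("C", "A & !B"),
                ("D", "!D & C"),
            ]
        )
        brute = sn.brute_force_attractors(net)
        reduced = sn.exhaustive_attractors(net, strategy="reduction", block_limit=3)
        assert set(reduced) == set(brute)

    def test_resource_cap_failure_names_the_residual(self):
        ring = sn.BooleanNetwork(
            [(f"R{i}", f"R{(i - 2) % 6 + 1}") for i in range(1, 7)]
        )
        with pytest.raises(ResourceCapExceeded, match="6 nodes"):
            sn.exhaustive_attractors(ring, strategy="reduction", block_limit=4)

    def test_direct_strategy_refuses_oversized_networks(self, sasp_model):
        with pytest.raises(ResourceCapExceeded):
            sn.exhaustive_attractors(sasp_model.network, strategy="direct")

    def test_sasp_network_attractor_count(self, sasp_model):
        atts = sn.exhaustive_attractors(sasp_model.network)
        assert len(atts) == 19


class TestAsynchronous:
    def test_oscillator_has_no_point_attractor(self):
        net = sn.BooleanNetwork([("X", "!X")])
        assert sn.async_point_attractors(net) == set()

    def test_copy_pair_fixed_points(self, two_node_copy_net):
        points = sn.async_point_attractors(two_node_copy_net)
        assert {s.bits for s in points} == {(0, 0), (1, 1)}

    def test_scheme_equivalence_subset(self, random_corpus, corpus_brute_attractors):
        for net, brute in zip(random_corpus[:50], corpus_brute_attractors[:50]):
            sync_fixed = {a.states[0] for a in brute if a.is_point}
            assert sn.async_point_attractors(net) == sync_fixed

    def test_reachability_sample_is_seeded_and_verified(self, sasp_model):
        net = sasp_model.network
        start = sasp_model.condition_state("dna_damage")
        a = sn.async_reachability_sample(net, start, walks=10, steps=500, seed=5)
        b = sn.async_reachability_sample(net, start, walks=10, steps=500, seed=5)
        assert a == b
        for state in a:
            assert sn.synchronous_step(net, state) == state

    def test_dna_damage_walks_reach_senescence_fixed_point(self, sasp_model):
        net = sasp_model.network
        start = sasp_model.condition_state("dna_damage")
        sync = sn.attractor_from_state(net, start).states[0]
        sampled = sn.async_reachability_sample(net, start, walks=20, steps=3000, seed=1)
        assert sync in sampled


class TestDiff:
    def test_identical_attractors_have_no_changes(self, sasp_model):
        att = sn.attractor_from_state(
            sasp_model.network, sasp_model.condition_state("baseline")
        )
        diff = sn.diff_attractors(att, att)
        assert diff.changed == ()

    def test_baseline_versus_dna_damage(self, sasp_model):
        net = sasp_model.network
        baseline = sn.attractor_from_state(net, sasp_model.condition_state("baseline"))
        damaged = sn.attractor_from_state(net, sasp_model.condition_state("dna_damage"))
        diff = sn.diff_attractors(baseline, damaged)
        assert {"CDK2", "CDK4", "E2F"} <= set(diff.changed)
        assert set(diff.changed) | set(diff.unchanged) == set(net.nodes)

    def test_cyclic_attractor_rejected(self):
        net = sn.BooleanNetwork([("X", "!X")])
        cyclic = sn.exhaustive_attractors(net)[0]
        with pytest.raises(ValueError, match="point"):
            sn.diff_attractors(cyclic, cyclic)
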