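import itertools
import re

import networkx as nx
import numpy as np
import pytest

from pathprocnet.bipartite_network import BipartiteNetwork
from pathprocnet.boolean_circuit import (
    BooleanCircuit,
    CircuitError,
    circuit_from_dict,
    circuit_to_dict,
    derive_circuit,
    evaluate,
    format_expression,
)


def eval_expression_bruteforce(expression: str, states: dict) -> int:
    """Truth-table oracle: evaluate the formatted text independently."""
    expr = expression
    for vid, value in states.items():
        expr = re.sub(rf"\b{re.escape(vid)}\b", str(bool(value)), expr)
    expr = expr.replace(" OR ", " or ").replace(" AND ", " and ")
    return int(eval(expr))  # noqa: S307 - controlled input in tests


def star_network(pathway, gobps):
    return BipartiteNetwork([(pathway, g, 0.5) for g in gobps], selection_cutoff=0.5)


class TestDeriveCircuit:
    def test_three_term_worked_configuration(self):
        # B1-B2 adjacent, B3 isolated: (B1 OR B2) AND (B3)
        net = star_network("P", ["B1", "B2", "B3"])
        term_graph = nx.Graph([("B1", "B2")])
        term_graph.add_node("B3")
        circuit = derive_circuit("P", net, term_graph)
        assert circuit.or_groups == (frozenset({"B1", "B2"}), frozenset({"B3"}))
        assert format_expression(circuit) == "(B1 OR B2) AND (B3)"

    def test_fully_connected_neighbors_pure_or(self):
        net = star_network("P", ["B1", "B2", "B3"])
        term_graph = nx.complete_graph(["B1", "B2", "B3"])
        circuit = derive_circuit("P", net, term_graph)
        assert circuit.or_groups == (frozenset({"B1", "B2", "B3"}),)

    def test_isolated_neighbors_pure_and(self):
        gobps = [f"B{i}" for i in range(1, 5)]
        net = star_network("P", gobps)
        term_graph = nx.Graph()
        term_graph.add_nodes_from(gobps)
        circuit = derive_circuit("P", net, term_graph)
        assert len(circuit.or_groups) == 4

    def test_chain_connectivity_is_path_connected(self):
        # B1-B2-B3 chain: all one OR group even though B1,B3 not adjacent
        net = star_network("P", ["B1", "B2", "B3"])
        circuit = derive_circuit("P", net, nx.path_graph(["B1", "B2", "B3"]))
        assert circuit.or_groups == (frozenset({"B1", "B2", "B3"}),)

    def test_neighbors_missing_from_term_graph_become_isolated(self):
        net = star_network("P", ["B1", "B2", "B9"])
        circuit = derive_circuit("P", net, nx.Graph([("B1", "B2")]))
        assert frozenset({"B9"}) in circuit.or_groups

    def test_groups_partition_neighbor_set_on_random_networks(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            gobps = [f"B{i}" for i in range(1, 11)]
            net = star_network("P", gobps)
            term_graph = nx.gnp_random_graph(10, 0.2, seed=trial)
            term_graph = nx.relabel_nodes(term_graph, {i: f"B{i + 1}" for i in range(10)})
            circuit = derive_circuit("P", net, term_graph)
            union = set().union(*circuit.or_groups)
            assert union == set(gobps)
            assert sum(len(g) for g in circuit.or_groups) == len(gobps)

    def test_pathway_without_neighbors_is_error(self):
        net = star_network("P", ["B1"])
        with pytest.raises(Exception):
            derive_circuit("Q", net, nx.Graph())


class TestEvaluate:
    @pytest.fixture
    def worked_circuit(self):
        return BooleanCircuit("P", (frozenset({"B1", "B2"}), frozenset({"B3"})))

    @pytest.mark.parametrize(
        "states,expected",
        [
            ({"B1": 1, "B2": 0, "B3": 1}, 1),
            ({"B1": 1, "B2": 1, "B3": 0}, 0),
            ({"B1": 1, "B2": 1, "B3": 1}, 1),
            ({"B1": 0, "B2": 0, "B3": 0}, 0),
        ],
    )
    def test_worked_example_assignments(self, worked_circuit, states, expected):
        assert evaluate(worked_circuit, states) == expected

    def test_missing_state_is_error(self, worked_circuit):
        with pytest.raises(CircuitError):
            evaluate(worked_circuit, {"B1": 1, "B2": 0})

    def test_unanimity_on_random_circuits(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(1, 9))
            splits = sorted(rng.choice(range(1, n + 1), size=min(3, n), replace=False))
            ids = [f"B{i}" for i in range(1, n + 1)]
            groups, prev = [], 0
            for s in splits:
                if s > prev:
                    groups.append(frozenset(ids[prev:s]))
                    prev = s
            if prev < n:
                groups.append(frozenset(ids[prev:]))
            circuit = BooleanCircuit("P", tuple(groups))
            assert evaluate(circuit, {i: 1 for i in ids}) == 1
            assert evaluate(circuit, {i: 0 for i in ids}) == 0

    def test_monotone_and_matches_formatted_truth_table(self):
        # exhaustive truth table up to 12 inputs: implementation vs eval of
        # the formatted expression, plus monotonicity on single bit flips
        configs = [[2, 1], [3, 2, 1], [1, 1, 1, 1], [4], [2, 2, 2, 2, 2, 2]]
        for groups_sizes in configs:
            n = sum(groups_sizes)
            ids = [f"B{i}" for i in range(1, n + 1)]
            groups, pos = [], 0
            for size in groups_sizes:
                groups.append(frozenset(ids[pos : pos + size]))
                pos += size
            circuit = BooleanCircuit("P", tuple(groups))
            expression = format_expression(circuit)
            for bits in itertools.product((0, 1), repeat=n):
                states = dict(zip(ids, bits))
                got = evaluate(circuit, states)
                assert got == eval_expression_bruteforce(expression, states)
                for i in range(n):
                    if bits[i] == 0:
                        flipped = dict(states)
                        flipped[ids[i]] = 1
                        assert evaluate(circuit, flipped) >= got


class TestSerialization:
    def test_expression_canonical_under_permutation(self):
        a = BooleanCircuit("P", (frozenset({"B3"}), frozenset({"B2", "B1"})))
        b = BooleanCircuit("P", (frozenset({"B1", "B2"}), frozenset({"B3"})))
        assert format_expression(a) == format_expression(b) == "(B1 OR B2) AND (B3)"

    def test_single_singleton_group(self):
        assert format_expression(BooleanCircuit("P", (frozenset({"B1"}),))) == "(B1)"

    def test_dict_roundtrip(self):
        circuit = BooleanCircuit("P", (frozenset({"B1", "B2"}), frozenset({"B3"})))
        assert circuit_from_dict(circuit_to_dict(circuit)) == circuit

    def test_overlapping_groups_rejected(self):
        with pytest.raises(CircuitError):
            BooleanCircuit("P", (frozenset({"B1"}), frozenset({"B1", "B2"})))
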