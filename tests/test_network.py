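"""Median-joining network construction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tests.conftest import make_matrix
from ylineage.network import (
    construct_mj_network,
    hamming,
    msn_edges,
    path_mutations,
    quasi_median,
)
from ylineage.simulate import SplitModelParams, simulate_split_haplotypes


def vec(s: str) -> np.ndarray:
    return np.array([int(c) for c in s], dtype=np.uint8)


class TestQuasiMedian:
    def test_sitewise_majority(self):
        med = quasi_median(vec("000"), vec("110"), vec("101"))
        assert med.tolist() == [1, 0, 0]

    def test_two_equal_vectors_win(self):
        x, y = vec("0110"), vec("1001")
        assert np.array_equal(quasi_median(x, x, y), x)

    def test_identity(self):
        x = vec("0101")
        assert np.array_equal(quasi_median(x, x, x), x)

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            u, v, w = (rng.integers(0, 2, size=8).astype(np.uint8)
                       for _ in range(3))
            med = quasi_median(u, v, w)
            # the majority vector minimises total Hamming cost to the triple
            best = min(
                (sum(hamming(np.array(c, dtype=np.uint8), x)
                     for x in (u, v, w))
                 for c in itertools.product([0, 1], repeat=8)),
            )
            assert sum(hamming(med, x) for x in (u, v, w)) == best


class TestConstruction:
    def test_two_haplotypes_one_edge(self):
        m = make_matrix({"a": "0000", "b": "1000"})
        net = construct_mj_network(m)
        observed = [n for n in net.graph if not net.graph.nodes[n]["is_median"]]
        assert net.graph.number_of_edges() >= 1
        assert path_mutations(net, "a", "b") == 1

    def test_median_insertion_reduces_cost(self):
        # {000, 110, 101} with root 000: the Steiner point 100 brings the
        # total connection cost down to 3
        m = make_matrix({"a": "000", "b": "110", "c": "101"})
        net = construct_mj_network(m, root_vector=vec("000"))
        medians = net.median_nodes()
        assert len(medians) == 1
        assert net.state(medians[0]).tolist() == [1, 0, 0]
        assert net.total_cost() == 3
        assert net.graph.nodes["a"]["is_root"]

    def test_identical_rows_collapse_with_multiplicity(self):
        m = make_matrix({"a": "01", "b": "01", "c": "11"})
        net = construct_mj_network(m)
        node = net.node_of_sample("a")
        assert net.graph.nodes[node]["multiplicity"] == 2
        assert node == net.node_of_sample("b")

    def test_missing_calls_rejected(self):
        m = make_matrix({"a": "0?", "b": "11"})
        with pytest.raises(ValueError, match="impute"):
            construct_mj_network(m)

    def test_root_attached_when_absent(self, tiny_matrix):
        net = construct_mj_network(
            tiny_matrix, root_vector=vec("111")
        )
        assert net.graph.nodes[net.root]["multiplicity"] == 0
        assert net.graph.nodes[net.root]["is_root"]
        net.validate()

    def test_table1_network_two_root_separated_haplogroups(
        self, table1_sequenced
    ):
        net = construct_mj_network(table1_sequenced)
        g = net.graph.copy()
        g.remove_node(net.root)
        comps = list(nx.connected_components(g))
        assert len(comps) == 2
        pops_by_comp = [
            {p for n in c for p in net.graph.nodes[n]["populations"]}
            for c in comps
        ]
        eurasian = {"Britain", "Iraq"}
        assert any(pops == eurasian for pops in pops_by_comp)
        other = next(p for p in pops_by_comp if p != eurasian)
        assert "Yamal, Siberia" in other
        assert any("USA" in p or "Canada" in p for p in other)

    def test_cost_never_increases_across_median_sweeps(self):
        for seed in range(5):
            m, _ = simulate_split_haplotypes(
                SplitModelParams(n_per_pop=10, seed=seed)
            )
            net = construct_mj_network(m)
            costs = net.meta["median_iteration_costs"]
            assert all(b <= a for a, b in zip(costs, costs[1:]))

    def test_msn_contained_in_network(self):
        for seed in (1, 2):
            m, _ = simulate_split_haplotypes(
                SplitModelParams(n_per_pop=6, seed=seed)
            )
            net = construct_mj_network(m)
            states = {n: net.state(n) for n in net.graph.nodes}
            for a, b in msn_edges(states, epsilon=0):
                assert net.graph.has_edge(a, b)

    def test_deterministic_construction(self, table1_sequenced):
        n1 = construct_mj_network(table1_sequenced)
        n2 = construct_mj_network(table1_sequenced)
        assert sorted(n1.graph.nodes) == sorted(n2.graph.nodes)
        assert sorted(map(sorted, n1.graph.edges)) == sorted(
            map(sorted, n2.graph.edges)
        )


class TestTreeRecovery:
    def test_infinite_sites_data_recovers_the_generating_tree(self):
        """On homoplasy-free two-clade data the network is exactly the
        genealogy: one median per unsampled ancestor, no reticulation."""
        for seed in range(100):
            m, truth = simulate_split_haplotypes(
                SplitModelParams(n_per_pop=6, t_total=1.0, t_clade=0.4,
                                 mu=4.0, seed=seed)
            )
            net = construct_mj_network(m)
            # homoplasy-free: network distances equal Hamming distances
            nodes = sorted(net.graph.nodes)
            for x, y in itertools.combinations(nodes, 2):
                assert path_mutations(net, x, y) == hamming(
                    net.state(x), net.state(y)
                )
            # the true nested-clade ancestor is present as a node
            assert net.node_for_state(truth.clade_ancestor) is not None
            # a tree after collapsing: edges = nodes - 1
            assert net.graph.number_of_edges() \
                == net.graph.number_of_nodes() - 1


class TestPathMutations:
    def test_root_to_britain_is_ten(self, table1_sequenced):
        net = construct_mj_network(table1_sequenced)
        brit = net.node_of_sample("S08-0428")
        assert path_mutations(net, net.root, brit) == 10

    def test_node_to_itself(self, tiny_matrix):
        net = construct_mj_network(tiny_matrix)
        assert path_mutations(net, "a", "a") == 0

    def test_unknown_node_raises(self, tiny_matrix):
        net = construct_mj_network(tiny_matrix)
        with pytest.raises(KeyError):
            path_mutations(net, "a", "nope")
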