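"""Newman modularity and Louvain optimization."""

import math
import random

import networkx as nx
import pytest

from peolc_topics.community import (
    LouvainCommunities,
    louvain_partition,
    modularity,
)
from peolc_topics.network import CooccurrenceNetwork

from conftest import exhaustive_best_modularity, naive_modularity


def _random_weighted_network(n_nodes, p_edge, seed):
    rng = random.Random(seed)
    g = nx.Graph()
    names = [f"t{i}" for i in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(names[i], names[j], weight=rng.uniform(0.1, 2.0))
    return CooccurrenceNetwork(graph=g)


class TestModularity:
    def test_all_one_community_is_zero(self, two_triangles):
        part = {v: 0 for v in two_triangles.nodes}
        assert modularity(two_triangles, part) == pytest.approx(0.0, abs=1e-15)

    def test_single_edge_singletons_minus_half(self, single_edge):
        assert modularity(single_edge, {"a": 0, "b": 1}) == pytest.approx(-0.5)

    def test_two_triangles_components_half(self, two_triangles):
        part = {v: (0 if v in "abc" else 1) for v in two_triangles.nodes}
        assert modularity(two_triangles, part) == pytest.approx(0.5, abs=1e-15)

    def test_missing_node_raises(self, two_triangles):
        with pytest.raises(ValueError, match="missing"):
            modularity(two_triangles, {"a": 0})

    def test_zero_weight_raises(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="zero"):
            modularity(CooccurrenceNetwork(graph=g), {"a": 0, "b": 0})

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_naive_double_loop(self, seed):
        net = _random_weighted_network(8, 0.5, seed)
        if net.graph.number_of_edges() == 0:
            return
        rng = random.Random(seed + 100)
        part = {v: rng.randint(0, 3) for v in net.nodes}
        assert modularity(net, part) == pytest.approx(
            naive_modularity(net.graph, part), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_networkx(self, seed):
        """Independent cross-check against networkx's implementation."""
        net = _random_weighted_network(10, 0.4, seed + 50)
        if net.graph.number_of_edges() == 0:
            return
        rng = random.Random(seed)
        part = {v: rng.randint(0, 2) for v in net.nodes}
        groups = {}
        for v, c in part.items():
            groups.setdefault(c, set()).add(v)
        expected = nx.community.modularity(
            net.graph, list(groups.values()), weight="weight"
        )
        assert modularity(net, part) == pytest.approx(expected, abs=1e-12)


class TestLouvain:
    def test_two_triangles_exact_optimum(self, two_triangles):
        part = louvain_partition(two_triangles, seed=0)
        assert part.modularity == pytest.approx(0.5, abs=1e-12)
        assert part.n_communities == 2
        comms = part.communities()
        assert sorted(map(sorted, comms.values())) == [list("abc"), list("xyz")]
        best_q, _ = exhaustive_best_modularity(two_triangles.graph)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)

    def test_four_clique_single_community(self, four_clique):
        part = louvain_partition(four_clique, seed=0)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-15)

    def test_planted_two_community_matches_exhaustive(self, planted_two_community):
        part = louvain_partition(planted_two_community, seed=0)
        best_q, best_blocks = exhaustive_best_modularity(
            planted_two_community.graph
        )
        assert part.modularity == pytest.approx(best_q, abs=1e-12)
        detected = sorted(map(sorted, part.communities().values()))
        assert detected == sorted(map(sorted, best_blocks))

    def test_fixed_seed_is_deterministic(self):
        net = _random_weighted_network(30, 0.2, 3)
        p1 = louvain_partition(net, seed=11)
        p2 = louvain_partition(net, seed=11)
        assert p1.assignment == p2.assignment
        assert p1.modularity == p2.modularity

    def test_edgeless_network_raises(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.raises(ValueError):
            louvain_partition(CooccurrenceNetwork(graph=g), seed=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_beats_singleton_partition(self, seed):
        net = _random_weighted_network(15, 0.3, seed + 10)
        if net.graph.number_of_edges() == 0:
            return
        part = louvain_partition(net, seed=0)
        singleton = {v: i for i, v in enumerate(net.nodes)}
        assert part.modularity >= modularity(net, singleton) - 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_never_exceeds_exhaustive_optimum_small(self, seed):
        net = _random_weighted_network(7, 0.45, seed + 70)
        if net.graph.number_of_edges() == 0:
            return
        part = louvain_partition(net, seed=0)
        best_q, _ = exhaustive_best_modularity(net.graph)
        assert part.modularity <= best_q + 1e-12

    def test_monotone_relabeling_equivariance(self, planted_two_community):
        """An order-preserving node renaming yields the same partition
        under the same seed path."""
        g = planted_two_community.graph
        mapping = {v: f"z_{i:02d}" for i, v in enumerate(sorted(g.nodes))}
        relabeled = CooccurrenceNetwork(graph=nx.relabel_nodes(g, mapping))
        p1 = louvain_partition(planted_two_community, seed=5)
        p2 = louvain_partition(relabeled, seed=5)
        assert {mapping[v]: c for v, c in p1.assignment.items()} == p2.assignment

    def test_community_ids_contiguous_from_zero(self):
        net = _random_weighted_network(20, 0.25, 9)
        part = louvain_partition(net, seed=0)
        ids = set(part.assignment.values())
        assert ids == set(range(part.n_communities))

    def test_agrees_with_networkx_louvain_quality(self):
        """Q attained is comparable to networkx's Louvain on the same
        graph (within the usual run-to-run wobble of the heuristic)."""
        net = _random_weighted_network(40, 0.15, 21)
        ours = louvain_partition(net, seed=0).modularity
        theirs = nx.community.modularity(
            net.graph,
            nx.community.louvain_communities(net.graph, weight="weight", seed=0),
            weight="weight",
        )
        assert ours >= theirs - 0.05


class TestLouvainEstimator:
    def test_fit_exposes_labels_and_modularity(self, two_triangles):
        clus = LouvainCommunities(seed=0).fit(two_triangles)
        assert clus.n_communities_ == 2
        assert clus.modularity_ == pytest.approx(0.5, abs=1e-12)
        assert len(clus.labels_) == 6

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        clus = LouvainCommunities(seed=3, tolerance=1e-9)
        assert clone(clus).get_params() == clus.get_params()
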