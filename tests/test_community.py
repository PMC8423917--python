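import itertools

import networkx as nx
import numpy as np
import pytest

from csnet.community import (
    CommunityPartition,
    community_composition,
    louvain,
    modularity,
)
from csnet.semnet import SemanticNetwork

from conftest import random_weighted_network


def net_from_edges(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return SemanticNetwork(g)


def two_triangles():
    return net_from_edges(
        [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)]
    )


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exhaustive_best_q(net):
    """Oracle: maximize modularity over every partition of the node set."""
    nodes = list(net.graph.nodes)
    best = -np.inf
    for partition in set_partitions(nodes):
        assignment = {}
        for cid, block in enumerate(partition):
            for node in block:
                assignment[node] = cid
        best = max(best, modularity(net, assignment))
    return best


class TestModularity:
    def test_single_community_gives_zero(self, rng):
        net = random_weighted_network(8, 0.6, rng)
        assignment = {u: 0 for u in net.graph.nodes}
        assert modularity(net, assignment) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_correct_split_is_half(self):
        net = two_triangles()
        assignment = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(net, assignment) == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_of_triangle(self):
        net = net_from_edges([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        assignment = {0: 0, 1: 1, 2: 2}
        assert modularity(net, assignment) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_missing_node_rejected(self):
        net = two_triangles()
        with pytest.raises(ValueError):
            modularity(net, {0: 0})

    def test_matches_networkx_on_random_partitions(self, rng):
        for _ in range(5):
            net = random_weighted_network(12, 0.4, rng)
            if net.n_edges() == 0:
                continue
            labels = rng.integers(0, 3, net.n_nodes())
            assignment = dict(zip(net.graph.nodes, (int(x) for x in labels)))
            groups = [
                {u for u, c in assignment.items() if c == cid}
                for cid in set(assignment.values())
            ]
            expected = nx.community.modularity(net.graph, groups, weight="weight")
            assert modularity(net, assignment) == pytest.approx(expected, abs=1e-12)


class TestLouvain:
    def test_recovers_two_disjoint_triangles(self):
        part = louvain(two_triangles(), seed=0)
        assert part.n_communities() == 2
        assert part.Q == pytest.approx(0.5, abs=1e-12)
        assert {frozenset(part.members(0)), frozenset(part.members(1))} == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        }

    def test_uniform_complete_graph_is_one_community(self):
        edges = [(u, v, 1.0) for u, v in itertools.combinations(range(6), 2)]
        part = louvain(net_from_edges(edges), seed=1)
        assert part.n_communities() == 1
        assert part.Q == pytest.approx(exhaustive_best_q(net_from_edges(edges)), abs=1e-9)

    def test_same_seed_gives_identical_assignment(self, rng):
        net = random_weighted_network(20, 0.3, rng)
        p1 = louvain(net, seed=42)
        p2 = louvain(net, seed=42)
        assert p1.assignment == p2.assignment

    def test_reported_q_matches_recomputation(self, rng):
        for seed in range(5):
            net = random_weighted_network(15, 0.35, np.random.default_rng(seed))
            if net.n_edges() == 0:
                continue
            part = louvain(net, seed=seed)
            assert part.Q == pytest.approx(modularity(net, part.assignment), abs=1e-9)

    def test_q_history_non_decreasing(self, rng):
        net = random_weighted_network(30, 0.2, rng)
        part = louvain(net, seed=3)
        assert all(b >= a - 1e-12 for a, b in zip(part.q_history, part.q_history[1:]))

    def test_matches_exhaustive_optimum_on_small_instances(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net = random_weighted_network(6, 0.5, rng)
            if net.n_edges() == 0:
                hits += 1
                continue
            part = louvain(net, seed=seed)
            if part.Q >= exhaustive_best_q(net) - 1e-9:
                hits += 1
        assert hits >= 9

    def test_community_ids_contiguous_and_size_ordered(self, rng):
        net = random_weighted_network(25, 0.15, rng)
        part = louvain(net, seed=5)
        ids = sorted(set(part.assignment.values()))
        assert ids == list(range(len(ids)))
        sizes = [len(part.members(c)) for c in ids]
        assert sizes == sorted(sizes, reverse=True)

    def test_edgeless_network_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            louvain(SemanticNetwork(g), seed=0)

    def test_agrees_with_networkx_louvain_quality(self, rng):
        # independent heuristic should find comparable modularity
        net = random_weighted_network(30, 0.25, rng)
        part = louvain(net, seed=0)
        nx_comms = nx.community.louvain_communities(net.graph, weight="weight", seed=0)
        q_nx = nx.community.modularity(net.graph, nx_comms, weight="weight")
        assert part.Q >= q_nx - 0.02


class TestComposition:
    def test_hand_counted_fixture(self):
        part = CommunityPartition(
            assignment={"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}, Q=0.1
        )
        tags = {"a": "es", "b": "es", "c": "en", "d": "en", "e": "other"}
        comp = community_composition(part, tags, l1="es", l2="en")
        row0 = comp[comp["community"] == 0].iloc[0]
        assert row0["n"] == 3
        assert row0["pct_l1"] == pytest.approx(200.0 / 3)
        assert row0["pct_l2"] == pytest.approx(100.0 / 3)
        row1 = comp[comp["community"] == 1].iloc[0]
        assert row1["pct_l2"] == pytest.approx(50.0)
        assert row1["pct_other"] == pytest.approx(50.0)
        assert (comp["pct_l1"] + comp["pct_l2"] + comp["pct_other"]).round(6).eq(100.0).all()
        assert list(comp["n"]) == sorted(comp["n"], reverse=True)

    def test_all_one_language_community(self):
        part = CommunityPartition(assignment={"x": 0, "y": 0}, Q=0.0)
        comp = community_composition(part, {"x": "en", "y": "en"}, l1="es", l2="en")
        assert comp.iloc[0]["pct_l2"] == pytest.approx(100.0)
        assert comp.iloc[0]["pct_l1"] == 0.0

    def test_missing_tag_rejected(self):
        part = CommunityPartition(assignment={"x": 0}, Q=0.0)
        with pytest.raises(ValueError):
            community_composition(part, {})
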