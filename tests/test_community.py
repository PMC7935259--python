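"""Modularity, fast gain, and Louvain recovery against exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from circnet.community import (
    community_gatekeepers,
    delta_q,
    louvain,
    modularity,
    undirected_view,
)
from circnet.centrality import BetweennessResult, node_betweenness

from conftest import net_from_edges


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def random_weighted_graph(rng, n, p=0.5):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j, weight=float(rng.integers(1, 6)))
    return g


def two_cliques(size=4, bridge_weight=1.0):
    g = nx.Graph()
    for offset, names in ((0, range(size)), (size, range(size, 2 * size))):
        for i, j in itertools.combinations(names, 2):
            g.add_edge(i, j, weight=1.0)
    g.add_edge(0, size, weight=bridge_weight)
    return g


class TestModularity:
    def test_single_community_is_zero(self):
        g = two_cliques()
        q = modularity(g, {u: 0 for u in g})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_singletons_closed_form(self):
        g = random_weighted_graph(np.random.default_rng(1), 7)
        k = dict(g.degree(weight="weight"))
        m = sum(d["weight"] for _, _, d in g.edges(data=True))
        expected = -sum((k[u] / (2 * m)) ** 2 for u in g)
        q = modularity(g, {u: i for i, u in enumerate(g)})
        assert q == pytest.approx(expected, abs=1e-12)

    def test_two_cliques_direct_evaluation(self):
        g = two_cliques(4)
        assign = {u: (0 if u < 4 else 1) for u in g}
        # direct double-sum evaluation as oracle
        k = dict(g.degree(weight="weight"))
        m = sum(d["weight"] for _, _, d in g.edges(data=True))
        a = nx.to_numpy_array(g, nodelist=sorted(g), weight="weight")
        nodes = sorted(g)
        q_direct = 0.0
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if assign[u] == assign[v]:
                    q_direct += a[i, j] - k[u] * k[v] / (2 * m)
        q_direct /= 2 * m
        assert modularity(g, assign) == pytest.approx(q_direct, abs=1e-12)

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = random_weighted_graph(rng, 8)
            if g.number_of_edges() == 0:
                continue
            assign = {u: int(rng.integers(0, 3)) for u in g}
            communities = {}
            for u, c in assign.items():
                communities.setdefault(c, set()).add(u)
            ref = nx.community.modularity(g, communities.values(), weight="weight")
            assert modularity(g, assign) == pytest.approx(ref, abs=1e-12)

    def test_zero_weight_errors(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            modularity(g, {0: 0, 1: 0})


class TestDeltaQ:
    def test_requires_isolated_node(self):
        g = two_cliques()
        assign = {u: (0 if u < 4 else 1) for u in g}
        with pytest.raises(ValueError):
            delta_q(g, 0, {4, 5, 6, 7}, assign)

    def test_zero_attachment_reduces_to_degree_penalty(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2.0)
        g.add_edge("c", "d", weight=1.0)
        assign = {"a": 0, "b": 0, "c": 1, "d": 2}
        # d has no edge to {a, b}: gain is pure degree penalty
        k = dict(g.degree(weight="weight"))
        m = 3.0
        expected = -2 * (k["a"] + k["b"]) * k["d"] / (2 * m) ** 2
        assert delta_q(g, "d", {"a", "b"}, assign) == pytest.approx(expected, abs=1e-12)

    def test_triangle_join(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=1.0)
        g.add_edge("a", "c", weight=1.0)
        assign = {"a": 0, "b": 0, "c": 1}
        before = modularity(g, assign)
        after = modularity(g, {"a": 0, "b": 0, "c": 0})
        assert delta_q(g, "c", {"a", "b"}, assign) == pytest.approx(after - before, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_every_candidate_move_matches_direct_difference(self, seed):
        """ΔQ ≡ direct modularity difference on exhaustive move sets, n ≤ 10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        g = random_weighted_graph(rng, n, p=0.6)
        if g.number_of_edges() == 0:
            return
        # random partition, then isolate each node in turn and try every community
        base = {u: int(rng.integers(0, 4)) for u in g}
        for node in g:
            assign = dict(base)
            assign[node] = max(base.values()) + 1  # isolate
            before = modularity(g, assign)
            communities = {}
            for u, c in assign.items():
                if u != node:
                    communities.setdefault(c, set()).add(u)
            for c, members in communities.items():
                moved = dict(assign)
                moved[node] = c
                direct = modularity(g, moved) - before
                fast = delta_q(g, node, members, assign)
                assert fast == pytest.approx(direct, abs=1e-12)


class TestLouvain:
    def test_two_cliques_recovered_and_exhaustively_optimal(self):
        g = two_cliques(4)
        part = louvain(g, seed=42)
        groups = {}
        for u, c in part.assignment.items():
            groups.setdefault(c, set()).add(u)
        assert set(map(frozenset, groups.values())) == {
            frozenset(range(4)),
            frozenset(range(4, 8)),
        }
        best = max(
            modularity(g, {u: i for i, block in enumerate(p) for u in block})
            for p in set_partitions(list(g))
        )
        assert part.modularity == pytest.approx(best, abs=1e-12)

    def test_no_community_spans_components(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_edge(1, 2, weight=1.0)
        g.add_edge(10, 11, weight=1.0)
        part = louvain(g, seed=1)
        assert part.assignment[0] != part.assignment[10]

    def test_reproducible_and_seed_sensitive_api(self):
        net = net_from_edges(
            [(f"N{i}", f"N{j}", int(w)) for i, j, w in
             np.random.default_rng(3).integers(0, 12, size=(40, 3)) if i != j and w > 0]
        )
        p1 = louvain(net, seed=7)
        p2 = louvain(net, seed=7)
        assert p1.assignment == p2.assignment
        assert p1.modularity == p2.modularity

    def test_stored_q_recomputable(self):
        g = two_cliques(5)
        part = louvain(g, seed=0)
        assert modularity(g, part.assignment) == pytest.approx(part.modularity, abs=1e-12)

    def test_q_at_least_trivial_partition(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            g = random_weighted_graph(rng, 9, p=0.4)
            if g.number_of_edges() == 0:
                continue
            assert louvain(g, seed=5).modularity >= -1e-12

    def test_edgeless_graph_errors(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        with pytest.raises(ValueError):
            louvain(g, seed=0)

    def test_optimality_gap_small_graphs(self):
        """Louvain Q vs exhaustive-partition optimum on n ≤ 8 graphs."""
        rng = np.random.default_rng(31)
        gaps = []
        for _ in range(5):
            g = random_weighted_graph(rng, 7, p=0.5)
            if g.number_of_edges() == 0:
                continue
            achieved = louvain(g, seed=11).modularity
            best = max(
                modularity(g, {u: i for i, block in enumerate(p) for u in block})
                for p in set_partitions(list(g))
            )
            assert achieved <= best + 1e-12
            gaps.append(best - achieved)
        assert max(gaps) <= 0.05


class TestGatekeepers:
    def test_highest_betweenness_member_per_community(self):
        net = net_from_edges(
            [("a", "b", 1), ("b", "c", 1), ("c", "a", 1), ("c", "d", 1),
             ("d", "e", 1), ("e", "f", 1), ("f", "d", 1)]
        )
        part = louvain(net, seed=2)
        nb = node_betweenness(net)
        gate = community_gatekeepers(part, nb)
        for c, node in gate.items():
            members = [u for u, cc in part.assignment.items() if cc == c]
            assert nb.scores[node] == max(nb.scores[m] for m in members)

    def test_single_and_singleton_community(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        part = louvain(net, seed=0)
        nb = node_betweenness(net)
        gate = community_gatekeepers(part, nb)
        assert set(gate) == set(part.assignment.values())
        scope_err = BetweennessResult("edge", {}, {})
        with pytest.raises(ValueError):
            community_gatekeepers(part, scope_err)
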