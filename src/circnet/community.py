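"""Louvain community detection on circulation networks.

Modularity compares the weight of edges inside communities with the
expectation under a degree-preserving null model:

    Q = 1/(2m) · Σ_ij [A_ij − k_i·k_j/(2m)] · δ(c_i, c_j)

with A the symmetric weighted adjacency, k_i the weighted degree and m the
total edge weight. The Louvain algorithm greedily maximizes Q in two
alternating phases: (1) sweep nodes in seeded-shuffle order, moving each to
the neighbouring community with the largest positive modularity gain, until
no move improves; (2) aggregate communities into super-nodes (internal
weight becomes a self-loop, parallel edges sum) and repeat on the smaller
graph until Q stabilizes.

The gain of absorbing an isolated node i into community C is computed from
community aggregates — with Σ_in the internal weight sum of C over ordered
pairs, Σ_tot its total degree, k_i,in the ordered-pair weight between i and
C, and k_i the degree of i:

    ΔQ = [(Σ_in + 2·k_i,in)/2m − ((Σ_tot + k_i)/2m)²]
       − [Σ_in/2m − (Σ_tot/2m)² − (k_i/2m)²]

which is verified in the test suite to equal the direct modularity
difference for every candidate move on exhaustive small graphs.

Directed circulation networks are symmetrized first — ω(u,v) and ω(v,u) are
summed — since the quality function is defined for undirected graphs; the
input network's self-loops (local circulation) are excluded throughout.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx

from circnet.build import CirculationNetwork
from circnet.centrality import BetweennessResult


def undirected_view(net: CirculationNetwork) -> nx.Graph:
    """Symmetrize a circulation network: ω_sym(u,v) = ω(u,v) + ω(v,u).

    Self-loops (within-unit circulation) are dropped; they carry no
    information about between-unit community structure.
    """
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for u, v, d in net.topology().edges(data=True):
        if g.has_edge(u, v):
            g[u][v]["weight"] += d["weight"]
        else:
            g.add_edge(u, v, weight=d["weight"])
    return g


def _as_graph(net_or_graph) -> nx.Graph:
    if isinstance(net_or_graph, CirculationNetwork):
        return undirected_view(net_or_graph)
    return net_or_graph


def _degrees_and_m(g: nx.Graph):
    # A_ii = 2w convention: networkx weighted degree already counts a
    # self-loop's weight twice, matching it
    k = dict(g.degree(weight="weight"))
    m = sum(d["weight"] for _, _, d in g.edges(data=True))
    return k, m


def modularity(net_or_graph, assignment: Mapping[Hashable, int], resolution: float = 1.0) -> float:
    """Evaluate Q exactly for a partition of an undirected weighted graph.

    Accepts a CirculationNetwork (symmetrized automatically) or an
    nx.Graph; self-loops on a plain graph are treated as internal weight of
    their node's community (the aggregated-graph convention).
    """
    g = _as_graph(net_or_graph)
    missing = [u for u in g if u not in assignment]
    if missing:
        raise ValueError(f"assignment misses nodes, e.g. {missing[:3]}")
    k, m = _degrees_and_m(g)
    if m <= 0:
        raise ValueError("modularity undefined: total edge weight is zero")
    two_m = 2.0 * m
    sigma_in: dict[int, float] = {}   # ordered-pair internal weight per community
    sigma_tot: dict[int, float] = {}  # total degree per community
    for u in g:
        c = assignment[u]
        sigma_tot[c] = sigma_tot.get(c, 0.0) + k[u]
    for u, v, d in g.edges(data=True):
        if assignment[u] == assignment[v]:
            c = assignment[u]
            sigma_in[c] = sigma_in.get(c, 0.0) + 2.0 * d["weight"]
    q = 0.0
    for c, tot in sigma_tot.items():
        q += sigma_in.get(c, 0.0) / two_m - resolution * (tot / two_m) ** 2
    return q


def delta_q(
    net_or_graph,
    node: Hashable,
    community: set,
    assignment: Mapping[Hashable, int],
    resolution: float = 1.0,
) -> float:
    """Fast modularity gain of absorbing an isolated node into a community.

    Precondition: ``node``'s current community contains only itself (the
    stated condition of the fast-gain formula); otherwise an error is
    raised — a general move is a removal (the reverse gain) followed by an
    insertion.
    """
    g = _as_graph(net_or_graph)
    own = assignment[node]
    mates = [u for u in g if assignment[u] == own and u != node]
    if mates:
        raise ValueError("delta_q requires the node to be alone in its community")
    if node in community:
        raise ValueError("node already belongs to the candidate community")
    k, m = _degrees_and_m(g)
    if m <= 0:
        raise ValueError("modularity undefined: total edge weight is zero")
    two_m = 2.0 * m
    sigma_tot = sum(k[u] for u in community)
    sigma_in = 0.0
    for u, v, d in g.edges(data=True):
        if u in community and v in community:
            sigma_in += 2.0 * d["weight"]
    k_i = k[node]
    k_i_in = sum(
        g[node][v]["weight"] for v in g.neighbors(node) if v in community and v != node
    )
    after = (sigma_in + 2.0 * k_i_in) / two_m - resolution * ((sigma_tot + k_i) / two_m) ** 2
    before = (
        sigma_in / two_m
        - resolution * (sigma_tot / two_m) ** 2
        - resolution * (k_i / two_m) ** 2
    )
    # the node's own self-loop term appears unchanged on both sides and cancels
    return after - before


@dataclass
class CommunityPartition:
    """Result of a Louvain run."""

    assignment: dict
    modularity: float
    levels: list = field(default_factory=list)  # per-iteration aggregated graphs
    seed: int = 0
    q_trace: list = field(default_factory=list)  # Q after each phase pair

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(ms, key=str) for c, ms in out.items()}


class _LouvainState:
    """Mutable bookkeeping for one local-move phase."""

    def __init__(self, g: nx.Graph, resolution: float):
        self.g = g
        self.resolution = resolution
        self.k, self.m = _degrees_and_m(g)
        self.two_m = 2.0 * self.m
        self.node2com = {u: i for i, u in enumerate(g.nodes)}
        self.tot = {self.node2com[u]: self.k[u] for u in g}
        # ordered-pair internal weight: initially only self-loops
        self.internal = {
            self.node2com[u]: 2.0 * g[u][u]["weight"] if g.has_edge(u, u) else 0.0 for u in g
        }

    def neighbour_weights(self, u):
        w: dict[int, float] = {}
        for v in self.g.neighbors(u):
            if v == u:
                continue
            c = self.node2com[v]
            w[c] = w.get(c, 0.0) + self.g[u][v]["weight"]
        return w

    def remove(self, u, w_to_com):
        c = self.node2com[u]
        self.tot[c] -= self.k[u]
        self.internal[c] -= 2.0 * w_to_com.get(c, 0.0)
        if self.g.has_edge(u, u):
            self.internal[c] -= 2.0 * self.g[u][u]["weight"]
        self.node2com[u] = -1

    def insert(self, u, c, w_to_com):
        self.node2com[u] = c
        self.tot[c] = self.tot.get(c, 0.0) + self.k[u]
        self.internal[c] = self.internal.get(c, 0.0) + 2.0 * w_to_com.get(c, 0.0)
        if self.g.has_edge(u, u):
            self.internal[c] += 2.0 * self.g[u][u]["weight"]

    def gain(self, u, c, w_to_com):
        # isolated-node fast gain against community c (node currently removed)
        k_i = self.k[u]
        tot = self.tot.get(c, 0.0)
        return (
            w_to_com.get(c, 0.0) / self.m
            - 2.0 * self.resolution * tot * k_i / (self.two_m * self.two_m)
        )

    def modularity(self) -> float:
        q = 0.0
        for c, tot in self.tot.items():
            q += self.internal.get(c, 0.0) / self.two_m - self.resolution * (tot / self.two_m) ** 2
        return q


def _one_phase(g: nx.Graph, rng: random.Random, resolution: float):
    state = _LouvainState(g, resolution)
    nodes = list(g.nodes)
    improved = True
    while improved:
        improved = False
        rng.shuffle(nodes)
        for u in nodes:
            w_to_com = state.neighbour_weights(u)
            old = state.node2com[u]
            state.remove(u, w_to_com)
            base = state.gain(u, old, w_to_com)  # gain of going back
            best_c, best_gain = old, base
            for c in sorted(w_to_com):
                gain = state.gain(u, c, w_to_com)
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            state.insert(u, best_c, w_to_com)
            if best_c != old:
                improved = True
    return state


def _aggregate(g: nx.Graph, node2com: Mapping) -> nx.Graph:
    agg = nx.Graph()
    agg.add_nodes_from(set(node2com.values()))
    for u, v, d in g.edges(data=True):
        cu, cv = node2com[u], node2com[v]
        w = d["weight"]
        if agg.has_edge(cu, cv):
            agg[cu][cv]["weight"] += w
        else:
            agg.add_edge(cu, cv, weight=w)
    return agg


def louvain(
    net_or_graph, seed: int = 42, resolution: float = 1.0
) -> CommunityPartition:
    """Two-phase Louvain modularity maximization.

    Deterministic given ``seed`` (which fixes the node sweep order); ties in
    gain break towards the lowest community id. Requires at least one
    (non-self-loop, for a circulation network) edge.
    """
    g0 = _as_graph(net_or_graph)
    if sum(d["weight"] for _, _, d in g0.edges(data=True)) <= 0:
        raise ValueError("louvain requires a graph with positive edge weight")
    rng = random.Random(seed)
    assignment = {u: u for u in g0.nodes}
    g = g0
    levels = []
    q_trace = []
    q_prev = None
    while True:
        state = _one_phase(g, rng, resolution)
        q = state.modularity()
        q_trace.append(q)
        # compose: original node -> phase community
        assignment = {u: state.node2com[assignment[u]] for u in assignment}
        g = _aggregate(g, state.node2com)
        levels.append(g)
        if q_prev is not None and q <= q_prev + 1e-12:
            break
        q_prev = q
    # renumber communities deterministically by their smallest member
    groups: dict[int, list] = {}
    for u, c in assignment.items():
        groups.setdefault(c, []).append(u)
    order = sorted(groups, key=lambda c: min(map(str, groups[c])))
    relabel = {c: i for i, c in enumerate(order)}
    final = {u: relabel[c] for u, c in assignment.items()}
    q_final = modularity(g0, final, resolution)
    return CommunityPartition(final, q_final, levels, seed, q_trace)


def community_gatekeepers(
    partition: CommunityPartition,
    betweenness: BetweennessResult,
    names: Mapping | None = None,
) -> dict[int, Hashable]:
    """Highest-betweenness member of each community (its network gatekeeper).

    Ties break lexicographically on the display name (or the node id when
    no name map is given).
    """
    if betweenness.scope != "node":
        raise ValueError("gatekeepers need node betweenness")
    names = names or {}
    best: dict[int, Hashable] = {}
    for node, c in partition.assignment.items():
        score = betweenness.scores.get(node, 0.0)
        if c not in best:
            best[c] = node
            continue
        cur = best[c]
        cur_score = betweenness.scores.get(cur, 0.0)
        if score > cur_score or (
            score == cur_score and str(names.get(node, node)) < str(names.get(cur, cur))
        ):
            best[c] = node
    return best
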