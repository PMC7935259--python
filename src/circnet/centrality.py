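"""Node and edge betweenness centrality on directed circulation networks.

Betweenness of a node k is the sum over ordered node pairs (i, j), i≠j≠k,
of the fraction of shortest i→j paths passing through k; edge betweenness is
the analogous per-edge passage fraction over all ordered pairs i≠j. Both are
computed exactly with Brandes' dependency-accumulation algorithm and
reported both raw and as percentages of the total (the share-of-total
presentation used for ranked key-path tables).

Distances default to hop counts: edge weights here are flow volumes, not
lengths, so treating weight as distance would invert the meaning. The
``weighted`` flag switches to distance = 1/weight (heavier flow = closer),
documented as non-default.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

from circnet.build import CirculationNetwork


@dataclass
class BetweennessResult:
    """Raw betweenness scores and their percentage shares of the total."""

    scope: str  # "node" or "edge"
    scores: dict
    percentages: dict

    def ranked(self) -> list[tuple]:
        """(target, raw score, percentage) sorted by score desc, then name."""
        return sorted(
            ((t, s, self.percentages[t]) for t, s in self.scores.items()),
            key=lambda row: (-row[1], str(row[0])),
        )


def _shortest_path_dag(g, source, weighted):
    """Single-source shortest paths: returns (order, predecessors, sigma).

    ``order`` lists settled nodes by non-decreasing distance, ``sigma`` the
    number of shortest paths from source. BFS for hop counts, Dijkstra with
    distance = 1/weight otherwise.
    """
    sigma = {v: 0.0 for v in g}
    pred = {v: [] for v in g}
    sigma[source] = 1.0
    order = []
    if not weighted:
        dist = {source: 0}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
    else:
        dist = {}
        seen = {source: 0.0}
        heap = [(0.0, source, None)]
        while heap:
            d, u, parent = heapq.heappop(heap)
            if u in dist:
                continue
            dist[u] = d
            order.append(u)
            for v in g.successors(u):
                length = 1.0 / g[u][v]["weight"]
                nd = d + length
                if v not in dist and (v not in seen or nd < seen[v] - 1e-15):
                    seen[v] = nd
                    heapq.heappush(heap, (nd, v, u))
                    sigma[v] = sigma[u]
                    pred[v] = [u]
                elif v not in dist and abs(nd - seen[v]) <= 1e-15:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
    return order, pred, sigma


def _brandes(g, weighted):
    node_score = {v: 0.0 for v in g}
    edge_score = {e: 0.0 for e in g.edges}
    for s in g:
        order, pred, sigma = _shortest_path_dag(g, s, weighted)
        delta = {v: 0.0 for v in g}
        for w in reversed(order):
            for u in pred[w]:
                contrib = sigma[u] / sigma[w] * (1.0 + delta[w])
                edge_score[(u, w)] += contrib
                delta[u] += contrib
            if w != s:
                node_score[w] += delta[w]
    return node_score, edge_score


def _percentages(scores):
    total = sum(scores.values())
    if total > 0:
        return {t: 100.0 * s / total for t, s in scores.items()}
    return {t: 0.0 for t in scores}


def node_betweenness(net: CirculationNetwork, weighted: bool = False) -> BetweennessResult:
    """Exact directed node betweenness (endpoints excluded, self-loops ignored)."""
    g = net.topology()
    if g.number_of_nodes() < 3:
        raise ValueError("node betweenness needs at least 3 nodes")
    node_score, _ = _brandes(g, weighted)
    return BetweennessResult("node", node_score, _percentages(node_score))


def edge_betweenness(net: CirculationNetwork, weighted: bool = False) -> BetweennessResult:
    """Exact directed edge betweenness over all ordered pairs i≠j."""
    g = net.topology()
    if g.number_of_nodes() < 3:
        raise ValueError("edge betweenness needs at least 3 nodes")
    _, edge_score = _brandes(g, weighted)
    return BetweennessResult("edge", edge_score, _percentages(edge_score))
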