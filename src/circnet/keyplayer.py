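"""Key-city identification by distance-weighted reach.

The reach of a node set S is the mean reciprocal shortest-path distance
from S to every node:

    D_R = (1/n) · Σ_i 1/d(S, i)

where d(S, i) is the minimum hop distance from any member of S to node i.
Members of S contribute 1 each (the self-distance convention of the
original key-player measure) and unreachable nodes contribute 0, so
D_R ∈ [0, 1] and D_R = 1 exactly when every node is in S or adjacent to it.

Sets are optimized with greedy forward selection followed by pairwise swap
improvement under seeded random restarts — the same heuristic family as the
original key-player software; exact subset enumeration stays feasible for
small n and is used as the oracle in tests.

Distances follow edge direction from S outward by default (circulation out
of the key cities); an undirected mode is available since the original
measure is undirected.
"""

from __future__ import annotations

import itertools
import random
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from circnet.build import CirculationNetwork


@dataclass
class KeyPlayerSolution:
    """A key-node set with its distance-weighted reach."""

    members: tuple
    reach: float
    search_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def reach_pct(self) -> float:
        return 100.0 * self.reach


def _adjacency(net: CirculationNetwork, directed: bool) -> dict:
    g = net.topology()
    adj = {u: set() for u in g}
    for u, v in g.edges:
        adj[u].add(v)
        if not directed:
            adj[v].add(u)
    return adj


def _reach(adj: dict, members) -> float:
    """Multi-source BFS evaluation of D_R."""
    n = len(adj)
    dist = {u: 0 for u in members}
    queue = deque(members)
    total = float(len(dist))
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                total += 1.0 / (du + 1)
                queue.append(v)
    return total / n


def distance_weighted_reach(
    net: CirculationNetwork, members, directed: bool = True
) -> float:
    """D_R of a node set: mean reciprocal hop distance from the set."""
    members = set(members)
    if not members:
        raise ValueError("the key-node set must be non-empty")
    unknown = members - set(net.graph.nodes)
    if unknown:
        raise ValueError(f"nodes not in network: {sorted(map(str, unknown))[:3]}")
    return _reach(_adjacency(net, directed), members)


def _swap_improve(adj, members: list, trace: list) -> tuple[list, float]:
    """Replace members pairwise while any swap raises D_R (best-improvement)."""
    current = _reach(adj, members)
    candidates = sorted(adj, key=str)
    improved = True
    while improved:
        improved = False
        inside = set(members)
        best = (current, None, None)
        for out_node in members:
            rest = [m for m in members if m != out_node]
            for in_node in candidates:
                if in_node in inside:
                    continue
                r = _reach(adj, rest + [in_node])
                if r > best[0] + 1e-12:
                    best = (r, out_node, in_node)
        if best[1] is not None:
            members = [m for m in members if m != best[1]] + [best[2]]
            trace.append(("swap", str(best[1]), str(best[2]), best[0]))
            current = best[0]
            improved = True
    return members, current


def find_key_players(
    net: CirculationNetwork,
    k: int,
    restarts: int = 20,
    seed: int = 42,
    directed: bool = True,
) -> KeyPlayerSolution:
    """Best k-node set under D_R: greedy + swap, with seeded random restarts.

    Restart 0 is deterministic greedy forward selection (ties towards the
    lexicographically smaller node) refined by swaps, so the result is never
    worse than pure greedy; further restarts start from random k-subsets.
    """
    adj = _adjacency(net, directed)
    n = len(adj)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    candidates = sorted(adj, key=str)
    trace: list = []

    # greedy forward selection
    members: list = []
    for _ in range(k):
        best_node, best_r = None, -1.0
        for c in candidates:
            if c in members:
                continue
            r = _reach(adj, members + [c])
            if r > best_r + 1e-12:
                best_node, best_r = c, r
        members.append(best_node)
        trace.append(("greedy_add", str(best_node), best_r))
    members, best_reach = _swap_improve(adj, members, trace)
    best_members = members

    rng = random.Random(seed)
    for _ in range(max(0, restarts - 1)):
        start = rng.sample(candidates, k)
        improved, r = _swap_improve(adj, start, [])
        if r > best_reach + 1e-12:
            best_reach, best_members = r, improved
            trace.append(("restart_improved", r))

    return KeyPlayerSolution(tuple(sorted(best_members, key=str)), best_reach, trace)


def exhaustive_key_players(
    net: CirculationNetwork, k: int, directed: bool = True
) -> KeyPlayerSolution:
    """Exact optimum by enumerating every C(n, k) subset (small n only)."""
    adj = _adjacency(net, directed)
    best, best_r = None, -1.0
    for combo in itertools.combinations(sorted(adj, key=str), k):
        r = _reach(adj, combo)
        if r > best_r + 1e-12:
            best, best_r = combo, r
    return KeyPlayerSolution(tuple(best), best_r, [("exhaustive", best_r)])


def key_player_profile(
    net: CirculationNetwork,
    k_max: int,
    restarts: int = 20,
    seed: int = 42,
    directed: bool = True,
) -> pd.DataFrame:
    """Reach-vs-set-size table: one independently optimized set per k.

    Sets need not be nested — membership can churn as k grows. The frame's
    ``attrs["full_cover_k"]`` records the smallest k (found by the same
    search) at which D_R reaches 1; None if not reached by n.
    """
    n = net.n_nodes
    if k_max > n:
        raise ValueError("k_max cannot exceed the number of nodes")
    rows = []
    full_cover_k = None
    names = {u: net.name_of(u) for u in net.graph.nodes}
    for k in range(1, k_max + 1):
        sol = find_key_players(net, k, restarts=restarts, seed=seed + k, directed=directed)
        rows.append(
            {
                "k": k,
                "members": ", ".join(sorted(names[m] for m in sol.members)),
                "reach": sol.reach,
                "reach_pct": sol.reach_pct,
            }
        )
        if full_cover_k is None and sol.reach >= 1.0 - 1e-12:
            full_cover_k = k
    k = k_max
    while full_cover_k is None and k < n:
        k += 1
        sol = find_key_players(net, k, restarts=max(1, restarts // 4), seed=seed + k, directed=directed)
        if sol.reach >= 1.0 - 1e-12:
            full_cover_k = k
    frame = pd.DataFrame(rows)
    frame.attrs["full_cover_k"] = full_cover_k
    return frame
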