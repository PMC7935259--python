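"""Descriptive statistics of circulation networks.

Per-node measures: unweighted in/out degree (distinct partners), weighted
in/out degree (record flows), the in/out flow ratio separating net
destinations (ratio > 1) from net sources (< 1), and circulation intensity —
substandard in- or out-flow per 1,000 samples inspected in the unit.
Network-level measures mirror the usual surveillance summary: size, directed
diameter, density e/(n(n−1)), weakly-connected components, means, medians
and ranges. Intensities are binned with Fisher–Jenks natural breaks into
Lower/Low/High/Higher classes, and the two class assignments combine into
four risk-pattern quadrants.

All statistics ignore self-loops: the within-unit mass is reported
separately by :func:`circnet.build.within_unit_fraction`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from circnet.build import CirculationNetwork

JENKS_LABELS_4 = ["Lower", "Low", "High", "Higher"]

PATTERN_A = "A_high_both"
PATTERN_B = "B_net_destination"
PATTERN_C = "C_net_source"
PATTERN_D = "D_low_both"
PATTERN_NONE = "unclassified"


def node_metrics(net: CirculationNetwork, weighted_ratio: bool = True) -> pd.DataFrame:
    """Per-node degree, flow and ratio table (self-loops excluded).

    Unweighted degrees count distinct in/out partners; weighted degrees sum
    record flows. The in/out ratio defaults to weighted flows (volume-based);
    ``weighted_ratio=False`` switches to partner counts. A node with zero
    out-flow but positive in-flow gets ratio +inf (pure destination); a node
    with neither gets NaN.
    """
    if net.n_nodes == 0:
        raise ValueError("node_metrics on an empty network")
    g = net.topology()
    rows = []
    for u in sorted(g.nodes):
        w_in = sum(d["weight"] for _, _, d in g.in_edges(u, data=True))
        w_out = sum(d["weight"] for _, _, d in g.out_edges(u, data=True))
        d_in = g.in_degree(u)
        d_out = g.out_degree(u)
        num, den = (w_in, w_out) if weighted_ratio else (d_in, d_out)
        if den > 0:
            ratio = num / den
        else:
            ratio = np.inf if num > 0 else np.nan
        rows.append(
            {
                "unit_id": u,
                "name": net.name_of(u),
                "in_degree": d_in,
                "out_degree": d_out,
                "degree": d_in + d_out,
                "weighted_in": w_in,
                "weighted_out": w_out,
                "weighted_degree": w_in + w_out,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def density(net: CirculationNetwork) -> float:
    """Directed density e / (n·(n−1)), self-loops excluded. Needs n ≥ 2."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density undefined for networks with fewer than 2 nodes")
    g = net.topology()
    return g.number_of_edges() / (n * (n - 1))


@dataclass
class NetworkSummary:
    """Network-level indicator block.

    ``mean_degree`` is e/n (each route counted once per network) with the
    per-endpoint convention 2e/n also reported; likewise for weighted
    degrees. The diameter is the longest shortest directed path over
    reachable pairs of the largest weakly-connected component;
    ``unreachable_pairs`` records how many ordered pairs had no directed
    path there.
    """

    size: int
    diameter: int
    density: float
    components: int
    strongly_connected: bool
    unreachable_pairs: int
    mean_degree: float
    mean_degree_per_endpoint: float
    mean_weighted_degree: float
    mean_weighted_degree_per_endpoint: float
    median_weighted_in: float
    range_weighted_in: tuple[float, float]
    median_weighted_out: float
    range_weighted_out: tuple[float, float]
    median_in_degree: float
    range_in_degree: tuple[float, float]
    median_out_degree: float
    range_out_degree: tuple[float, float]

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(net: CirculationNetwork) -> NetworkSummary:
    """Compute the standard indicator table for one network."""
    g = net.topology()
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("summarize on an empty network")
    metrics = node_metrics(net)
    e = g.number_of_edges()
    components = nx.number_weakly_connected_components(g)
    largest = max(nx.weakly_connected_components(g), key=len)
    sub = g.subgraph(largest)
    diam = 0
    reachable_pairs = 0
    for src, dists in nx.all_pairs_shortest_path_length(sub):
        for dst, d in dists.items():
            if dst == src:
                continue
            reachable_pairs += 1
            diam = max(diam, d)
    total_pairs = len(largest) * (len(largest) - 1)
    mass = metrics["weighted_in"].sum()  # == weighted_out sum, cross-unit records

    def med_range(col):
        s = metrics[col]
        return float(s.median()), (float(s.min()), float(s.max()))

    mwi, rwi = med_range("weighted_in")
    mwo, rwo = med_range("weighted_out")
    mdi, rdi = med_range("in_degree")
    mdo, rdo = med_range("out_degree")
    return NetworkSummary(
        size=n,
        diameter=diam,
        density=density(net) if n >= 2 else 0.0,
        components=components,
        strongly_connected=nx.is_strongly_connected(g) if n else False,
        unreachable_pairs=total_pairs - reachable_pairs,
        mean_degree=e / n,
        mean_degree_per_endpoint=2 * e / n,
        mean_weighted_degree=mass / n,
        mean_weighted_degree_per_endpoint=2 * mass / n,
        median_weighted_in=mwi,
        range_weighted_in=rwi,
        median_weighted_out=mwo,
        range_weighted_out=rwo,
        median_in_degree=mdi,
        range_in_degree=rdi,
        median_out_degree=mdo,
        range_out_degree=rdo,
    )


def circulation_intensity(
    metrics: pd.DataFrame, totals: Mapping[str, float], per: float = 1000.0
) -> pd.DataFrame:
    """Add substandard flow per ``per`` inspected samples to the metrics table.

    ``totals`` maps unit_id → total samples inspected in the unit (qualified
    plus substandard). Units without a positive total are flagged
    ``unscorable`` with NaN intensities rather than silently zeroed.
    """
    out = metrics.copy()
    tot = out["unit_id"].map(lambda u: totals.get(u, np.nan)).astype(float)
    scorable = tot > 0
    out["total_samples"] = tot
    out["unscorable"] = ~scorable
    out["in_intensity"] = np.where(scorable, per * out["weighted_in"] / tot, np.nan)
    out["out_intensity"] = np.where(scorable, per * out["weighted_out"] / tot, np.nan)
    return out


def _ssd(prefix_sum, prefix_sq, i, j):
    # within-class sum of squared deviations of sorted values[i..j] inclusive
    n = j - i + 1
    s = prefix_sum[j + 1] - prefix_sum[i]
    sq = prefix_sq[j + 1] - prefix_sq[i]
    return sq - s * s / n


def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Fisher–Jenks optimal natural breaks.

    Finds the partition of the sorted values into ``k`` contiguous classes
    minimizing total within-class sum of squared deviations, by dynamic
    programming (exact, O(k·n²)). Returns k+1 class edges
    ``[min, lower bound of class 2, ..., max]``: class ``c`` is the
    half-open interval [edges[c], edges[c+1]), the last class closed.

    Requires at least ``k`` distinct values.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least {k} distinct values, got {len(np.unique(vals))}")
    prefix_sum = np.concatenate([[0.0], np.cumsum(vals)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(vals**2)])

    # cost[c][j] = minimal SSD of splitting vals[0..j] into c+1 classes
    INF = np.inf
    cost = np.full((k, n), INF)
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        cost[0][j] = _ssd(prefix_sum, prefix_sq, 0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = INF, c
            for i in range(c, j + 1):  # class c starts at index i
                cand = cost[c - 1][i - 1] + _ssd(prefix_sum, prefix_sq, i, j)
                if cand < best:
                    best, arg = cand, i
            cost[c][j] = best
            back[c][j] = arg
    # recover class start indices
    starts = [0] * k
    j = n - 1
    for c in range(k - 1, 0, -1):
        starts[c] = int(back[c][j])
        j = starts[c] - 1
    edges = [float(vals[0])]
    edges += [float(vals[s]) for s in starts[1:]]
    edges.append(float(vals[-1]))
    return edges


def jenks_classes(
    values: Sequence[float], k: int = 4, labels: Sequence[str] | None = None
) -> tuple[list[float], list[str]]:
    """Classify values into natural-breaks classes.

    Returns (edges, per-value labels). For k=4 the default labels are
    Lower/Low/High/Higher in ascending order. Intervals are half-open
    [lo, hi) except the topmost, which is closed.
    """
    if labels is None:
        labels = JENKS_LABELS_4 if k == 4 else [f"class_{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must equal k")
    edges = jenks_breaks(values, k)
    assigned = [labels[assign_class(v, edges)] for v in values]
    return edges, assigned


def assign_class(value: float, edges: Sequence[float]) -> int:
    """Index of the natural-breaks class containing ``value``."""
    k = len(edges) - 1
    for c in range(k - 1):
        if edges[c] <= value < edges[c + 1]:
            return c
    return k - 1


def classify_patterns(
    metrics: pd.DataFrame,
    in_col: str = "intensity_class_in",
    out_col: str = "intensity_class_out",
) -> pd.DataFrame:
    """Assign risk-pattern quadrants from intensity classes.

    A: both intensities in the top class (high circulation both ways);
    B: in-intensity top but out not (net destination of risk);
    C: out-intensity top but in not (net source);
    D: both in the bottom class (low circulation); else unclassified.
    """
    top, bottom = JENKS_LABELS_4[-1], JENKS_LABELS_4[0]

    def pattern(row):
        hi_in = row[in_col] == top
        hi_out = row[out_col] == top
        if hi_in and hi_out:
            return PATTERN_A
        if hi_in:
            return PATTERN_B
        if hi_out:
            return PATTERN_C
        if row[in_col] == bottom and row[out_col] == bottom:
            return PATTERN_D
        return PATTERN_NONE

    out = metrics.copy()
    out["pattern"] = out.apply(pattern, axis=1)
    return out


def intensity_class_table(metrics: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Attach natural-breaks classes for both intensities; returns new frame.

    Adds ``intensity_class_in`` / ``intensity_class_out`` columns and stores
    the class edges in ``frame.attrs["jenks_edges"]``.
    """
    out = metrics.copy()
    edges = {}
    for direction in ("in", "out"):
        col = f"{direction}_intensity"
        scorable = out[col].notna()
        e, lab = jenks_classes(out.loc[scorable, col].tolist(), k)
        out.loc[scorable, f"intensity_class_{direction}"] = lab
        edges[direction] = e
    out.attrs["jenks_edges"] = edges
    return out
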