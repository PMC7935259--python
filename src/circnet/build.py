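"""Construction of directed weighted circulation networks.

A node is an administrative unit (province or city); a directed edge
u → v carries the number of substandard records manufactured in u and
distributed in v. Records staying inside one unit become self-loops: they
carry the "local circulation" mass and are reported through
:func:`within_unit_fraction`, but are excluded from degree-based topology
statistics (degree, density, betweenness, communities, key players), which
matches the default behaviour of standard network-analysis tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from circnet.geocode import CITY, PROVINCE, GeoResolution

logger = logging.getLogger(__name__)


@dataclass
class CirculationNetwork:
    """A directed weighted circulation network at one admin level.

    ``graph`` is a networkx DiGraph whose nodes are unit ids with ``name``
    (and for cities ``parent_id``/``parent_name``) attributes and whose
    edges carry integer ``weight`` counts, self-loops included.
    """

    level: str
    graph: nx.DiGraph
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def name_of(self, node) -> str:
        return self.graph.nodes[node].get("name", str(node))

    @property
    def total_weight(self) -> int:
        """Sum of all edge weights, self-loops included = records represented."""
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    @property
    def self_loop_weight(self) -> int:
        return sum(self.graph[u][u]["weight"] for u in nx.nodes_with_selfloops(self.graph))

    def topology(self) -> nx.DiGraph:
        """The graph without self-loops, used by all topology statistics."""
        g = self.graph.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
        return g

    # ---- exports --------------------------------------------------------
    def to_edgelist_csv(self, path, include_self_loops: bool = True) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "destination", "weight"])
            rows = [
                (self.name_of(u), self.name_of(v), d["weight"])
                for u, v, d in self.graph.edges(data=True)
                if include_self_loops or u != v
            ]
            writer.writerows(sorted(rows))

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_gexf(self, path) -> None:
        nx.write_gexf(self.graph, path)


def _unit_at_level(resolved, level):
    return resolved.city if level == CITY else resolved.province


def build_network(resolutions: list[GeoResolution], level: str) -> CirculationNetwork:
    """Count record flows manufacturer-unit → distributor-unit at one level.

    Resolutions lacking a unit at the requested level are skipped with an
    explicit count in ``meta["skipped_unresolved"]``. An empty input yields
    an empty network with a warning.
    """
    if level not in (PROVINCE, CITY):
        raise ValueError(f"level must be {PROVINCE!r} or {CITY!r}")
    g = nx.DiGraph()
    skipped = 0
    for res in resolutions:
        src = _unit_at_level(res.manufacturer, level)
        dst = _unit_at_level(res.distributor, level)
        if src is None or dst is None:
            skipped += 1
            continue
        for unit in (src, dst):
            if unit.unit_id not in g:
                attrs = {"name": unit.name, "level": unit.level}
                if unit.parent_id:
                    attrs["parent_id"] = unit.parent_id
                g.add_node(unit.unit_id, **attrs)
        if g.has_edge(src.unit_id, dst.unit_id):
            g[src.unit_id][dst.unit_id]["weight"] += 1
        else:
            g.add_edge(src.unit_id, dst.unit_id, weight=1)
    if g.number_of_nodes() == 0:
        logger.warning("no resolvable records at level %s: empty network", level)
    if skipped:
        logger.info("build_network(%s): skipped %d unresolved records", level, skipped)
    return CirculationNetwork(level, g, {"skipped_unresolved": skipped, "records_used": len(resolutions) - skipped})


def within_unit_fraction(net: CirculationNetwork) -> float:
    """Share of circulation staying inside a single unit (self-loop mass / total)."""
    total = net.total_weight
    if total == 0:
        raise ValueError("within_unit_fraction undefined on a zero-weight network")
    return net.self_loop_weight / total


def top_paths(
    net: CirculationNetwork, k: int, exclude_self_loops: bool = True
) -> list[tuple[str, str, int]]:
    """The k heaviest circulation routes, by record count.

    Ties are broken by (source name, destination name) lexicographically so
    the ranking is reproducible. Cross-unit routes only, unless
    ``exclude_self_loops`` is False.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = [
        (net.name_of(u), net.name_of(v), d["weight"])
        for u, v, d in net.graph.edges(data=True)
        if not (exclude_self_loops and u == v)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows[:k]


def aggregate_to_parent(net: CirculationNetwork) -> CirculationNetwork:
    """Aggregate a city-level network to province level by summing flows.

    Cross-city flows inside one province become province self-loops, so the
    province network's weight mass equals the city network's exactly.
    """
    if net.level != CITY:
        raise ValueError("aggregate_to_parent expects a city-level network")
    g = nx.DiGraph()
    for u, v, d in net.graph.edges(data=True):
        pu = net.graph.nodes[u].get("parent_id")
        pv = net.graph.nodes[v].get("parent_id")
        if pu is None or pv is None:
            raise ValueError(f"city node without parent_id: {u if pu is None else v}")
        for pid in (pu, pv):
            if pid not in g:
                g.add_node(pid, name=pid, level=PROVINCE)
        if g.has_edge(pu, pv):
            g[pu][pv]["weight"] += d["weight"]
        else:
            g.add_edge(pu, pv, weight=d["weight"])
    # carry province display names if the city nodes know them
    for u, data in net.graph.nodes(data=True):
        pid = data.get("parent_id")
        pname = data.get("parent_name")
        if pid in g and pname:
            g.nodes[pid]["name"] = pname
    return CirculationNetwork(PROVINCE, g, dict(net.meta))
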