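"""Shared fixtures and graph-building helpers."""

from __future__ import annotations

import networkx as nx
import pandas as pd
import pytest

from circnet.build import CirculationNetwork
from circnet.geocode import AdminUnit, Gazetteer
from circnet.records import CANONICAL_COLUMNS, RecordSet


def net_from_edges(edges, level="city", parents=None):
    """CirculationNetwork from (source, destination, weight) triples."""
    g = nx.DiGraph()
    parents = parents or {}
    nodes = {u for u, v, _ in edges} | {v for _, v, _ in edges}
    for u in nodes:
        attrs = {"name": str(u), "level": level}
        if u in parents:
            attrs["parent_id"] = parents[u]
        g.add_node(u, **attrs)
    for u, v, w in edges:
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return CirculationNetwork(level, g)


def record_frame(rows):
    """DataFrame in canonical order from partial row dicts."""
    frame = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = None
    return frame[CANONICAL_COLUMNS]


def record_set(rows) -> RecordSet:
    return RecordSet(record_frame(rows))


@pytest.fixture
def demo_gazetteer() -> Gazetteer:
    """Two provinces, four cities, with aliases and a municipality."""
    units = [
        AdminUnit("shanxi", "Shanxi", "province", centroid=(112.5, 37.8)),
        AdminUnit("guangdong", "Guangdong", "province"),
        AdminUnit("chongqing", "Chongqing", "province"),
        AdminUnit("jinzhong", "Jinzhong", "city", parent_id="shanxi", centroid=(112.75, 37.68)),
        AdminUnit("taiyuan", "Taiyuan", "city", parent_id="shanxi"),
        AdminUnit("guangzhou", "Guangzhou", "city", parent_id="guangdong"),
        AdminUnit("chongqing_c", "Chongqing", "city", parent_id="chongqing"),
    ]
    return Gazetteer(units, aliases={"guangzhou": ["Canton"]})
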