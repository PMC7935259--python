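"""Descriptive statistics: degrees, density, summary, intensity, Jenks, patterns."""

import itertools

import numpy as np
import pandas as pd
import pytest

from circnet.stats import (
    JENKS_LABELS_4,
    PATTERN_A,
    PATTERN_C,
    PATTERN_D,
    assign_class,
    circulation_intensity,
    classify_patterns,
    density,
    jenks_breaks,
    jenks_classes,
    node_metrics,
    summarize,
)

from conftest import net_from_edges


def _row(metrics, name):
    return metrics.set_index("name").loc[name]


class TestNodeMetrics:
    def test_star_center(self):
        net = net_from_edges([("S", "A", 1), ("S", "B", 1), ("S", "C", 1)])
        row = _row(node_metrics(net), "S")
        assert row["out_degree"] == 3 and row["in_degree"] == 0
        assert row["weighted_degree"] == 3
        assert row["ratio"] == 0.0

    def test_weighted_ratio_and_inf_sentinel(self):
        net = net_from_edges([("A", "B", 4), ("B", "A", 2), ("C", "B", 1)])
        metrics = node_metrics(net)
        assert _row(metrics, "B")["ratio"] == pytest.approx((4 + 1) / 2)
        assert not np.isinf(_row(metrics, "A")["ratio"])
        assert _row(metrics, "A")["ratio"] == pytest.approx(2 / 4)
        # C only sends: ratio 0; a pure sink gets +inf
        net2 = net_from_edges([("A", "B", 3)])
        m2 = node_metrics(net2)
        assert np.isinf(_row(m2, "B")["ratio"])

    def test_self_loops_excluded_from_degrees(self):
        net = net_from_edges([("A", "A", 10), ("A", "B", 1)])
        row = _row(node_metrics(net), "A")
        assert row["degree"] == 1 and row["weighted_degree"] == 1

    def test_unweighted_ratio_flag(self):
        net = net_from_edges([("A", "B", 100), ("B", "A", 1), ("C", "A", 1)])
        weighted = _row(node_metrics(net), "A")["ratio"]
        unweighted = _row(node_metrics(net, weighted_ratio=False), "A")["ratio"]
        assert weighted == pytest.approx(2 / 100)
        assert unweighted == pytest.approx(2 / 1)

    def test_handshake_sums(self):
        rng = np.random.default_rng(3)
        edges = [
            (f"N{i}", f"N{j}", int(rng.integers(1, 9)))
            for i in range(8)
            for j in range(8)
            if i != j and rng.random() < 0.4
        ]
        net = net_from_edges(edges)
        m = node_metrics(net)
        e = net.topology().number_of_edges()
        assert m["in_degree"].sum() == m["out_degree"].sum() == e
        cross_mass = sum(w for _, _, w in edges)
        assert m["weighted_in"].sum() == m["weighted_out"].sum() == cross_mass


class TestDensityAndSummary:
    def test_complete_and_dyad(self):
        complete = net_from_edges(
            [(a, b, 1) for a, b in itertools.permutations("ABC", 2)]
        )
        assert density(complete) == 1.0
        dyad = net_from_edges([("A", "B", 1)])
        assert density(dyad) == 0.5

    def test_density_needs_two_nodes(self):
        with pytest.raises(ValueError):
            density(net_from_edges([("A", "A", 1)]))

    def test_density_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            edges = [
                (f"N{i}", f"N{j}", 1)
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < 0.5
            ]
            if not edges:
                continue
            net = net_from_edges(edges)
            nodes = net.n_nodes
            assert density(net) == pytest.approx(len(set((u, v) for u, v, _ in edges)) / (nodes * (nodes - 1)))

    def test_path_summary(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 1)])
        s = summarize(net)
        assert s.diameter == 2 and s.components == 1
        assert not s.strongly_connected
        assert s.unreachable_pairs == 3  # b->a, c->a, c->b

    def test_disconnected_dyads(self):
        net = net_from_edges([("a", "b", 1), ("c", "d", 1)])
        assert summarize(net).components == 2

    def test_mean_degree_conventions(self):
        net = net_from_edges([("a", "b", 3), ("b", "c", 5)])
        s = summarize(net)
        assert s.mean_degree == pytest.approx(2 / 3)
        assert s.mean_degree_per_endpoint == pytest.approx(4 / 3)
        assert s.mean_weighted_degree == pytest.approx(8 / 3)
        assert s.mean_weighted_degree_per_endpoint == pytest.approx(16 / 3)


class TestIntensity:
    def test_per_thousand_arithmetic(self):
        net = net_from_edges([("A", "B", 130)])
        m = node_metrics(net)
        scored = circulation_intensity(m, {"B": 2000, "A": 1000})
        assert _row(scored, "B")["in_intensity"] == pytest.approx(65.0)
        assert _row(scored, "B")["out_intensity"] == 0.0
        assert _row(scored, "A")["out_intensity"] == pytest.approx(130.0)

    def test_missing_totals_flagged_not_zeroed(self):
        net = net_from_edges([("A", "B", 5)])
        scored = circulation_intensity(node_metrics(net), {"A": 100})
        row = _row(scored, "B")
        assert row["unscorable"]
        assert np.isnan(row["in_intensity"])


def _jenks_oracle(values, k):
    """Exhaustive search over all contiguous break placements."""
    vals = sorted(values)
    n = len(vals)

    def ssd(chunk):
        mean = sum(chunk) / len(chunk)
        return sum((x - mean) ** 2 for x in chunk)

    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(ssd(vals[bounds[i]:bounds[i + 1]]) for i in range(k))
        if cost < best_cost - 1e-12:
            best_cost, best = cost, bounds
    edges = [vals[0], *[vals[b] for b in best[1:-1]], vals[-1]]
    return edges, best_cost


class TestJenks:
    def test_forced_gaps(self):
        values = [1, 2, 10, 11, 100, 101, 1000, 1001]
        edges = jenks_breaks(values, 4)
        assert edges == [1, 10, 100, 1000, 1001]

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            jenks_breaks([5, 5, 5, 5], 2)
        with pytest.raises(ValueError):
            jenks_breaks([1, 2, 3], 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.gamma(2.0, 10.0, size=22), 2).tolist()
        k = 4
        edges = jenks_breaks(values, k)
        oracle_edges, oracle_cost = _jenks_oracle(values, k)

        def cost_of(edges):
            classes = [assign_class(v, edges) for v in values]
            total = 0.0
            for c in range(k):
                chunk = [v for v, cl in zip(values, classes) if cl == c]
                if chunk:
                    mean = sum(chunk) / len(chunk)
                    total += sum((x - mean) ** 2 for x in chunk)
            return total

        assert cost_of(edges) == pytest.approx(oracle_cost)

    def test_labels_and_interval_convention(self):
        values = [1.0, 2.0, 10.0, 11.0, 100.0, 101.0, 1000.0, 1001.0]
        edges, labels = jenks_classes(values, 4)
        assert labels == ["Lower", "Lower", "Low", "Low", "High", "High", "Higher", "Higher"]
        # half-open below, closed top: a boundary value belongs to the upper class
        assert assign_class(10.0, edges) == 1
        assert assign_class(1001.0, edges) == 3


class TestPatterns:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_quadrants(self):
        frame = self._frame(
            [
                {"name": "A-unit", "intensity_class_in": "Higher", "intensity_class_out": "Higher"},
                {"name": "C-unit", "intensity_class_in": "Low", "intensity_class_out": "Higher"},
                {"name": "D-unit", "intensity_class_in": "Lower", "intensity_class_out": "Lower"},
                {"name": "mid", "intensity_class_in": "Low", "intensity_class_out": "High"},
            ]
        )
        out = classify_patterns(frame)
        by = out.set_index("name")["pattern"]
        assert by["A-unit"] == PATTERN_A
        assert by["C-unit"] == PATTERN_C
        assert by["D-unit"] == PATTERN_D
        assert by["mid"] == "unclassified"


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=8, max_size=25),
    st.integers(min_value=2, max_value=4),
)
def test_jenks_break_structure_properties(values, k):
    """Edges are sorted data values spanning [min, max]; classes partition."""
    if len(set(values)) < k:
        with pytest.raises(ValueError):
            jenks_breaks(values, k)
        return
    edges = jenks_breaks(values, k)
    assert len(edges) == k + 1
    assert edges == sorted(edges)
    assert edges[0] == min(values) and edges[-1] == max(values)
    assert set(edges) <= set(values)
    for v in values:
        c = assign_class(v, edges)
        assert 0 <= c < k


def test_net_destination_count_invariant_under_relabeling():
    rng = np.random.default_rng(12)
    edges = [
        (f"N{i}", f"N{j}", int(rng.integers(1, 20)))
        for i in range(10)
        for j in range(10)
        if i != j and rng.random() < 0.3
    ]
    net = net_from_edges(edges)
    m1 = node_metrics(net)
    relabeled = net_from_edges([(u + "_x", v + "_x", w) for u, v, w in edges])
    m2 = node_metrics(relabeled)
    assert (m1["ratio"] > 1).sum() == (m2["ratio"] > 1).sum()
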