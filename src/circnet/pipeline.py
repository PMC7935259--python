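"""End-to-end orchestration: clean → geocode → build → analyse → report.

`analyze` runs the whole analysis in memory and returns a result bundle;
`run_all` wraps it with file I/O, writing every report table (network
summaries, ratio and intensity tables, top paths, betweenness rankings,
communities with gatekeepers, key-player profile) plus a single JSON
manifest in which every number carries the name of the operation that
produced it. Identical inputs and seeds give byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from circnet import build as _build
from circnet import centrality as _centrality
from circnet import community as _community
from circnet import keyplayer as _keyplayer
from circnet import stats as _stats
from circnet.geocode import CITY, PROVINCE, Gazetteer, resolve_records, resolutions_to_frame
from circnet.records import SUBSTANDARD, RecordSet, clean_records, filter_substandard, load_records

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective configuration of one full pipeline run."""

    records_path: str
    gazetteer_path: str
    out_dir: str
    column_map: dict = field(default_factory=dict)
    levels: tuple = (PROVINCE, CITY)
    seed: int = 42
    n_classes: int = 4
    k_max: int = 10
    restarts: int = 10
    top_k_paths: int = 10
    encoding: str = "utf-8"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload["levels"] = tuple(payload.get("levels", (PROVINCE, CITY)))
        return cls(**payload)


def quarterly_counts(rs: RecordSet) -> pd.DataFrame:
    """Per-calendar-quarter record counts and substandard proportion.

    Undated records are excluded from the table and reported in
    ``frame.attrs["undated"]``; an empty table (no dated records) is legal
    and warned about.
    """
    frame = rs.frame
    dated = frame[frame["sample_date"].notna()].copy()
    undated = len(frame) - len(dated)
    if dated.empty:
        logger.warning("quarterly_counts: no dated records")
        out = pd.DataFrame(columns=["quarter", "total", "substandard", "proportion"])
        out.attrs["undated"] = undated
        return out
    quarters = pd.PeriodIndex(pd.to_datetime(dated["sample_date"]), freq="Q")
    dated["quarter"] = quarters.astype(str)
    grouped = dated.groupby("quarter").agg(
        total=("record_id", "size"),
        substandard=("status", lambda s: int((s == SUBSTANDARD).sum())),
    )
    grouped["proportion"] = grouped["substandard"] / grouped["total"]
    out = grouped.reset_index().sort_values("quarter").reset_index(drop=True)
    out.attrs["undated"] = undated
    return out


def analyze(
    records: RecordSet,
    gazetteer: Gazetteer,
    levels: tuple = (PROVINCE, CITY),
    seed: int = 42,
    n_classes: int = 4,
    k_max: int = 10,
    restarts: int = 10,
    top_k_paths: int = 10,
) -> dict:
    """Run the full analysis in memory; returns a nested result bundle.

    Intensity denominators (total samples per unit) are taken from the full
    cleaned record set — qualified and substandard — counted at each
    record's distributor (sampling) unit.
    """
    results: dict = {"seed": seed}

    cleaned, report = clean_records(records)
    results["cleaning"] = {"operation": "clean_records", **report}
    results["counts"] = cleaned.counts

    substandard = filter_substandard(cleaned)
    results["substandard_count"] = len(substandard)

    res_all = resolve_records(cleaned, gazetteer)
    # resolutions of the substandard subset, aligned by record_id
    sub_ids = set(substandard.frame["record_id"])
    res_sub = [r for r in res_all if r.record_id in sub_ids]
    n_unres = sum(r.unresolved for r in res_all)
    results["geocoding"] = {
        "operation": "resolve_records",
        "records": len(res_all),
        "unresolved": n_unres,
    }

    # totals per unit for intensity: full record set, by distributor unit
    totals: dict[str, dict[str, float]] = {PROVINCE: {}, CITY: {}}
    for r in res_all:
        for level, unit in ((PROVINCE, r.distributor.province), (CITY, r.distributor.city)):
            if unit is not None:
                totals[level][unit.unit_id] = totals[level].get(unit.unit_id, 0) + 1

    results["quarterly"] = {
        "operation": "quarterly_counts",
        "table": quarterly_counts(cleaned).to_dict(orient="records"),
    }

    results["levels"] = {}
    networks = {}
    for level in levels:
        net = _build.build_network(res_sub, level)
        networks[level] = net
        if net.n_nodes == 0:
            results["levels"][level] = {"empty": True}
            continue
        level_out: dict = {"empty": False}
        level_out["within_unit_fraction"] = {
            "operation": "within_unit_fraction",
            "value": _build.within_unit_fraction(net),
        }
        summary = _stats.summarize(net)
        level_out["summary"] = {"operation": "summarize", **summary.to_dict()}
        metrics = _stats.node_metrics(net)
        finite = metrics["ratio"].replace([np.inf], np.nan)
        level_out["ratio_table"] = {
            "operation": "node_metrics",
            "net_destinations": int((metrics["ratio"] > 1).sum()),
            "net_sources": int((finite < 1).sum()),
            "balanced": int((finite == 1).sum()),
        }
        metrics = _stats.circulation_intensity(metrics, totals[level])
        scorable = metrics["in_intensity"].notna() & metrics["out_intensity"].notna()
        if scorable.sum() >= n_classes and metrics.loc[scorable, "in_intensity"].nunique() >= n_classes \
                and metrics.loc[scorable, "out_intensity"].nunique() >= n_classes:
            metrics = _stats.intensity_class_table(metrics, k=n_classes)
            metrics = _stats.classify_patterns(metrics)
            level_out["intensity_classes"] = {
                "operation": "jenks_classes",
                "edges": metrics.attrs["jenks_edges"],
                "patterns": metrics["pattern"].value_counts().to_dict(),
            }
        level_out["top_paths"] = {
            "operation": "top_paths",
            "paths": _build.top_paths(net, top_k_paths),
        }
        if net.n_nodes >= 3:
            nb = _centrality.node_betweenness(net)
            eb = _centrality.edge_betweenness(net)
            level_out["node_betweenness"] = {
                "operation": "node_betweenness",
                "top": [(net.name_of(t), s, p) for t, s, p in nb.ranked()[:10]],
            }
            level_out["edge_betweenness"] = {
                "operation": "edge_betweenness",
                "top": [
                    (net.name_of(u), net.name_of(v), s, p)
                    for (u, v), s, p in eb.ranked()[:10]
                ],
            }
        level_out["metrics_frame"] = metrics
        results["levels"][level] = level_out

    # community structure + key players on the city network, when present
    if CITY in networks and networks[CITY].graph.number_of_edges() > 0:
        net = networks[CITY]
        topo = net.topology()
        if topo.number_of_edges() > 0:
            partition = _community.louvain(net, seed=seed)
            nb = _centrality.node_betweenness(net) if net.n_nodes >= 3 else None
            gate = (
                _community.community_gatekeepers(
                    partition, nb, names={u: net.name_of(u) for u in net.graph.nodes}
                )
                if nb
                else {}
            )
            results["communities"] = {
                "operation": "louvain",
                "n_communities": partition.n_communities,
                "modularity": partition.modularity,
                "gatekeepers": {int(c): net.name_of(u) for c, u in sorted(gate.items())},
                "assignment": {net.name_of(u): int(c) for u, c in sorted(partition.assignment.items())},
            }
            k_cap = min(k_max, net.n_nodes)
            profile = _keyplayer.key_player_profile(
                net, k_cap, restarts=restarts, seed=seed
            )
            results["key_players"] = {
                "operation": "key_player_profile",
                "profile": profile.to_dict(orient="records"),
                "full_cover_k": profile.attrs["full_cover_k"],
            }

    results["_networks"] = networks
    return results


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Run every stage from files and persist all report tables + manifest.

    Any stage failure aborts with the stage name in the raised error. The
    effective configuration is echoed into the output directory; the
    manifest holds every reported number with the operation that produced
    it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        records = load_records(
            config.records_path, column_map=config.column_map, encoding=config.encoding
        )
        gaz = Gazetteer.from_csv(config.gazetteer_path)
        stage = "analyze"
        results = analyze(
            records,
            gaz,
            levels=tuple(config.levels),
            seed=config.seed,
            n_classes=config.n_classes,
            k_max=config.k_max,
            restarts=config.restarts,
            top_k_paths=config.top_k_paths,
        )
        stage = "write"
        for level, net in results["_networks"].items():
            net.to_edgelist_csv(out / f"network_{level}.csv")
            net.to_graphml(out / f"network_{level}.graphml")
            net.to_gexf(out / f"network_{level}.gexf")
            level_out = results["levels"].get(level, {})
            frame = level_out.get("metrics_frame")
            if isinstance(frame, pd.DataFrame):
                frame.to_csv(out / f"metrics_{level}.csv", index=False)
                level_out["metrics_frame"] = f"metrics_{level}.csv"
        manifest = {
            "config": {**dataclasses.asdict(config), "levels": list(config.levels)},
            "results": _jsonify(results),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "effective_config.json", "w", encoding="utf-8") as fh:
            json.dump(manifest["config"], fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}; re-run with "
            f"`circnet run-all --records {config.records_path} "
            f"--gazetteer {config.gazetteer_path} --out {config.out_dir}`"
        ) from exc
    return manifest
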