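"""End-to-end pipeline: ingest -> filter/score -> network -> hubs -> enrichment.

The whole analysis is deterministic: randomness exists only in the
synthetic-data generator. A run writes every intermediate table plus a
``report.json`` with per-stage counts, a config echo and input checksums;
rerunning on identical inputs reproduces byte-identical data outputs (the
report differs only in its timestamp).
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .enrichment import (
    AnnotationMap,
    EnrichMethod,
    enrich,
    read_annotation,
    write_enrichment_table,
)
from .ingest import (
    DEFAULT_DIALECTS,
    DbDialect,
    DbName,
    Direction,
    InteractionRecord,
    MirnaExpression,
    ParseReport,
    load_dialects,
    read_expression_table,
    read_gene_map,
    read_interaction_db,
    write_parse_reports,
)
from .network import (
    BipartiteNetwork,
    HubMode,
    build_network,
    excluded_mirnas,
    export_edge_list,
    export_graphml,
    select_hubs,
    venn_partition,
)
from .scoring import ScoringConfig, score_interactions, write_scored_table
from .synthetic import GeneratorConfig, emit_files, generate

__all__ = ["load_config", "run_pipeline", "simulate_inputs", "DB_FILE_KEYS"]

logger = logging.getLogger(__name__)

DB_FILE_KEYS = (
    "mirdb",
    "microrna_org_conserved",
    "microrna_org_nonconserved",
    "mirtarbase",
)

#: enrichment study sets the pipeline knows how to assemble
STUDY_SETS = ("up_targets", "down_targets", "common_targets", "all_targets", "hubs")
DEFAULT_STUDY_SETS = ("up_targets", "down_targets", "common_targets", "hubs")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a run config (YAML or JSON); input paths resolve relative to it."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = cfg or {}
    cfg.setdefault("inputs", {})
    base = path.parent
    for key, val in list(cfg["inputs"].items()):
        if val:
            cfg["inputs"][key] = str((base / val).resolve())
    return cfg


def _scoring_config(cfg: Mapping[str, Any], **overrides: Any) -> ScoringConfig:
    params = dict(cfg.get("scoring") or {})
    params.update({k: v for k, v in overrides.items() if v is not None})
    return ScoringConfig(**params)


def _dialects(cfg: Mapping[str, Any]) -> dict[str, DbDialect]:
    spec = cfg.get("dialects")
    if not spec:
        return dict(DEFAULT_DIALECTS)
    out = {}
    for key, default in DEFAULT_DIALECTS.items():
        entry = spec.get(key) or {}
        out[key] = DbDialect(
            db_name=DbName(entry.get("db_name", default.db_name.value)),
            column_map=entry.get("columns", dict(default.column_map)),
            header_rows=entry.get("header_rows", default.header_rows),
            delimiter=entry.get("delimiter", default.delimiter),
        )
    return out


def ingest_stage(
    cfg: Mapping[str, Any]
) -> tuple[list[MirnaExpression], list[InteractionRecord], list[ParseReport]]:
    """Read the expression table and all four database files."""
    inputs = cfg["inputs"]
    prefix = cfg.get("species_prefix", "rno")
    expressions = read_expression_table(inputs["expression"], species_prefix=prefix)
    gene_map = (
        read_gene_map(inputs["gene_map"]) if inputs.get("gene_map") else None
    )
    dialects = _dialects(cfg)
    records: list[InteractionRecord] = []
    reports: list[ParseReport] = []
    for key in DB_FILE_KEYS:
        recs, report = read_interaction_db(
            inputs[key], dialects[key], species_prefix=prefix, gene_map=gene_map
        )
        records.extend(recs)
        reports.append(report)
    return expressions, records, reports


def _study_sets(
    network: BipartiteNetwork, hub_table, requested: list[str]
) -> dict[str, set[str]]:
    up = {
        g
        for (m, g) in network.edges
        if network.mirna_nodes[m] is Direction.UP
    }
    down = {
        g
        for (m, g) in network.edges
        if network.mirna_nodes[m] is Direction.DOWN
    }
    available = {
        "up_targets": up,
        "down_targets": down,
        "common_targets": up & down,
        "all_targets": set(network.gene_nodes),
        "hubs": set(hub_table.loc[hub_table["is_hub"], "gene_id"]),
    }
    unknown = set(requested) - set(available)
    if unknown:
        raise ValueError(f"unknown enrichment study sets: {sorted(unknown)}")
    return {name: available[name] for name in requested}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    hub_mode: str | None = None,
    min_degree: int | None = None,
    enrich_method: str | None = None,
    alpha: float | None = None,
) -> dict[str, Any]:
    """Execute the full analysis and write all outputs plus report.json."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scoring_cfg = _scoring_config(cfg, hub_min_degree=min_degree)
    mode = HubMode(hub_mode or cfg.get("hub_mode", "total"))
    ecfg = cfg.get("enrichment") or {}
    method = EnrichMethod(enrich_method or ecfg.get("method", "hypergeometric"))
    alpha_val = alpha if alpha is not None else float(ecfg.get("alpha", 0.05))
    requested_sets = list(ecfg.get("study_sets", DEFAULT_STUDY_SETS))

    # ingest + score
    expressions, records, reports = ingest_stage(cfg)
    write_parse_reports(reports, out / "parse_report.tsv")
    scored = score_interactions(records, scoring_cfg)
    write_scored_table(scored, out / "scored_interactions.tsv")
    retained = [s for s in scored if s.retained]

    # network
    network = build_network(scored, expressions)
    export_graphml(network, out / "network.graphml")
    export_edge_list(network, out / "edge_list.tsv")
    excl_up, excl_down = excluded_mirnas(expressions, network)
    with (out / "excluded_mirnas.tsv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna_id", "direction"])
        for m in excl_up:
            writer.writerow([m, "up"])
        for m in excl_down:
            writer.writerow([m, "down"])
    venn = venn_partition(network)
    with (out / "venn_counts.tsv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["up_only", "down_only", "both", "union_total", "naive_sum"])
        writer.writerow(
            [venn.up_only, venn.down_only, venn.both, venn.union_total, venn.naive_sum]
        )

    # hubs
    hub_table = select_hubs(network, scoring_cfg, mode)
    hub_table.to_csv(out / "hub_table.tsv", sep="\t", index=False)

    # enrichment
    enriched_terms = 0
    enrichment_counts: dict[str, dict[str, int]] = {}
    annotation_path = cfg["inputs"].get("annotation")
    if annotation_path:
        annotation = read_annotation(annotation_path)
        for name, genes in _study_sets(network, hub_table, requested_sets).items():
            if not genes & annotation.background:
                logger.warning("study set %s empty or unannotated; skipped", name)
                enrichment_counts[name] = {"n_genes": len(genes), "n_enriched": 0}
                continue
            results = enrich(genes, annotation, alpha=alpha_val, method=method)
            write_enrichment_table(results, out / f"enrichment_{name}.tsv")
            n_enriched = sum(r.enriched for r in results)
            enrichment_counts[name] = {
                "n_genes": len(genes),
                "n_enriched": n_enriched,
            }
            enriched_terms += n_enriched

    report = {
        "tool": "mirhub",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": {
            "scoring": scoring_cfg.__dict__,
            "hub_mode": mode.value,
            "enrichment": {
                "method": method.value,
                "alpha": alpha_val,
                "study_sets": requested_sets,
            },
            "species_prefix": cfg.get("species_prefix", "rno"),
        },
        "input_checksums": {
            key: _sha256(p)
            for key, p in cfg["inputs"].items()
            if p and Path(p).exists()
        },
        "counts": {
            "mirnas_differential": len(expressions),
            "records_read": {r.file: r.rows_read for r in reports},
            "records_kept": {r.file: r.rows_kept for r in reports},
            "distinct_pairs": len(scored),
            "retained_pairs": len(retained),
            "network_mirnas": len(network.mirna_nodes),
            "network_genes": len(network.gene_nodes),
            "network_edges": network.n_edges,
            "excluded_up": len(excl_up),
            "excluded_down": len(excl_down),
            "venn": {
                "up_only": venn.up_only,
                "down_only": venn.down_only,
                "both": venn.both,
                "union_total": venn.union_total,
                "naive_sum": venn.naive_sum,
            },
            "hub_count": int(hub_table["is_hub"].sum()),
            "enriched_terms": enriched_terms,
            "enrichment": enrichment_counts,
        },
    }
    with (out / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def simulate_inputs(
    out_dir: str | Path, seed: int = 0, **generator_overrides: Any
) -> Path:
    """Generate synthetic inputs and a ready-to-run config; return config path."""
    out = Path(out_dir)
    config = GeneratorConfig(seed=seed, **generator_overrides)
    truth = generate(config)
    emit_files(truth, config, out)
    run_cfg = {
        "species_prefix": "rno",
        "inputs": {
            "expression": "expression.tsv",
            "mirdb": "mirdb.tsv",
            "microrna_org_conserved": "microrna_org_conserved.tsv",
            "microrna_org_nonconserved": "microrna_org_nonconserved.tsv",
            "mirtarbase": "mirtarbase.tsv",
            "annotation": "annotation.tsv",
        },
        "hub_mode": "total",
        "enrichment": {
            "method": "hypergeometric",
            "alpha": 0.05,
            "study_sets": list(DEFAULT_STUDY_SETS),
        },
    }
    cfg_path = out / "config.yaml"
    with cfg_path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return cfg_path
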