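"""Seeded generator of synthetic pipeline inputs with planted ground truth.

The generator emulates the shape of the study the pipeline was designed
for: ~47 upregulated and ~10 downregulated miRNAs, three interaction
databases with partially overlapping content, a handful of high-degree hub
mRNAs, a few miRNAs whose only evidence is a single predicted database
(and which therefore drop out of the network), and GO terms planted to be
over-represented among target genes. Every planted structure is recorded
in a :class:`GroundTruth` object so each pipeline stage has an exact
expected answer.

Construction guarantees (not merely high probability):

* every *true* interaction survives the evidence rules — it is echoed into
  a second predicted database with probability ``db_overlap_prob`` and is
  otherwise forced into the validated database;
* decoy records never survive — they either carry a filter-failing score
  or passing single-predicted-database membership (and a pair never
  receives passing decoys in both predicted databases);
* planted hub genes have exactly ``planted_hub_degree`` true interactions
  while every other gene stays strictly below the hub threshold, so hub
  recovery is exact in both the noise-free and the default noisy regime.

Identifiers are synthetic (``rno-mir-sim-u001``, ``GENE0001``) to avoid
implying real biology; ``use_printed_hub_names`` substitutes eleven real
rat gene symbols for the planted hubs in documentation examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ingest import Direction, MirnaExpression

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "emit_files"]

#: Real rat hub gene symbols, available for documentation examples.
PRINTED_HUB_NAMES = (
    "ADRB2", "CASK", "LPPR4", "MOB4", "MYT1L", "PPP3R1",
    "PTH", "PTPRZ1", "SGK1", "STX1A", "WEE1",
)

_SUPPORT_TYPES = ("Functional MTI", "Functional MTI (Weak)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study shape the pipeline targets: 47 up / 10 down
    miRNAs of which 4 and 2 are planted to fail the inclusion criteria,
    11 hub mRNAs, and score distributions placed on the passing/failing
    sides of the published quality-filter boundaries (miRDB target scores
    pass above 80.0, mirSVR scores pass below -1.2; failing mirSVR decoys
    include the exact boundary value).
    """

    seed: int = 0
    n_up: int = 47
    n_down: int = 10
    n_genes: int = 500
    n_planted_hubs: int = 11
    planted_hub_degree: int = 5
    n_excluded_up: int = 4
    n_excluded_down: int = 2
    db_overlap_prob: float = 0.7
    validated_prob: float = 0.3
    decoy_rate: float = 0.3
    duplicate_site_prob: float = 0.2
    hub_min_degree: int = 4
    # probability of a non-hub gene having 0,1,2,3 true regulators
    nonhub_degree_probs: tuple[float, ...] = (0.5, 0.25, 0.15, 0.10)
    mirdb_true_range: tuple[float, float] = (81.0, 100.0)
    mirdb_fail_range: tuple[float, float] = (50.0, 80.0)
    mirsvr_true_range: tuple[float, float] = (-3.0, -1.205)
    mirsvr_fail_range: tuple[float, float] = (-1.1999, -0.0001)
    n_terms: int = 40
    planted_term_count: int = 3
    planted_term_effect: float = 0.8
    background_term_rate: float = 0.1
    use_printed_hub_names: bool = False

    def __post_init__(self) -> None:
        for p in (
            self.db_overlap_prob,
            self.validated_prob,
            self.decoy_rate,
            self.duplicate_site_prob,
            self.planted_term_effect,
            self.background_term_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.planted_hub_degree < self.hub_min_degree:
            raise ValueError("planted_hub_degree must reach the hub threshold")
        n_active = (
            self.n_up + self.n_down - self.n_excluded_up - self.n_excluded_down
        )
        if self.planted_hub_degree > n_active:
            raise ValueError(
                "planted_hub_degree exceeds the number of network miRNAs"
            )
        if self.n_excluded_up > self.n_up or self.n_excluded_down > self.n_down:
            raise ValueError("cannot exclude more miRNAs than exist")
        if self.n_planted_hubs > self.n_genes:
            raise ValueError("more planted hubs than genes")
        if self.use_printed_hub_names and self.n_planted_hubs > len(PRINTED_HUB_NAMES):
            raise ValueError("not enough printed hub names")
        if abs(sum(self.nonhub_degree_probs) - 1.0) > 1e-9:
            raise ValueError("nonhub_degree_probs must sum to 1")
        if len(self.nonhub_degree_probs) > self.hub_min_degree:
            raise ValueError("non-hub degree support must stay below the hub threshold")
        if self.planted_term_count > self.n_terms:
            raise ValueError("more planted terms than terms")


@dataclass
class GroundTruth:
    """Everything the generator planted, plus the emitted file contents."""

    expressions: list[MirnaExpression]
    true_interactions: set[tuple[str, str]]
    planted_hubs: set[str]
    excluded_up: list[str]
    excluded_down: list[str]
    planted_terms: set[str]
    target_genes: set[str]
    annotation_pairs: list[tuple[str, str, str]]
    # pre-rendered file rows, keyed by input-file name
    file_rows: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)


def _round(x: float, nd: int = 4) -> float:
    return float(np.round(x, nd))


def generate(config: GeneratorConfig) -> GroundTruth:
    """Draw one synthetic study; deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)

    up_ids = [f"rno-mir-sim-u{i + 1:03d}" for i in range(config.n_up)]
    down_ids = [f"rno-mir-sim-d{i + 1:03d}" for i in range(config.n_down)]
    expressions = [MirnaExpression(m, Direction.UP) for m in up_ids] + [
        MirnaExpression(m, Direction.DOWN) for m in down_ids
    ]
    excluded_up = sorted(
        rng.choice(up_ids, size=config.n_excluded_up, replace=False).tolist()
    )
    excluded_down = sorted(
        rng.choice(down_ids, size=config.n_excluded_down, replace=False).tolist()
    )
    excluded = set(excluded_up) | set(excluded_down)
    active = [m for m in up_ids + down_ids if m not in excluded]

    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    hub_idx = rng.choice(config.n_genes, size=config.n_planted_hubs, replace=False)
    if config.use_printed_hub_names:
        for rank, i in enumerate(sorted(hub_idx)):
            genes[i] = PRINTED_HUB_NAMES[rank]
    hubs = {genes[i] for i in hub_idx}

    # --- true interactions ------------------------------------------------
    true_pairs: set[tuple[str, str]] = set()
    degree: dict[str, int] = {g: 0 for g in genes}
    mirna_degree: dict[str, int] = {m: 0 for m in active}
    degrees_support = np.arange(len(config.nonhub_degree_probs))
    for gene in genes:
        if gene in hubs:
            deg = config.planted_hub_degree
        else:
            deg = int(rng.choice(degrees_support, p=config.nonhub_degree_probs))
        if deg == 0:
            continue
        chosen = rng.choice(active, size=deg, replace=False)
        for m in chosen:
            true_pairs.add((str(m), gene))
            mirna_degree[str(m)] += 1
        degree[gene] = deg
    # every non-excluded miRNA must keep >= 1 retained interaction, else it
    # would wrongly appear in the excluded report; attach orphans to a gene
    # with spare sub-threshold capacity
    for m in active:
        if mirna_degree[m] > 0:
            continue
        candidates = sorted(
            g
            for g in genes
            if g not in hubs
            and degree[g] < config.hub_min_degree - 1
            and (m, g) not in true_pairs
        )
        gene = str(rng.choice(candidates))
        true_pairs.add((m, gene))
        degree[gene] += 1
        mirna_degree[m] += 1

    # --- database membership and scores -----------------------------------
    rows_mirdb: list[tuple[str, ...]] = []
    rows_morg_cons: list[tuple[str, ...]] = []
    rows_morg_noncons: list[tuple[str, ...]] = []
    rows_mtb: list[tuple[str, ...]] = []

    def morg_row(m: str, g: str, score: float) -> None:
        row = (m, g, f"{score:.4f}")
        if rng.random() < 0.5:
            rows_morg_cons.append(row)
        else:
            rows_morg_noncons.append(row)

    for m, g in sorted(true_pairs):
        primary_is_mirdb = bool(rng.random() < 0.5)
        echoed = bool(rng.random() < config.db_overlap_prob)
        validated = bool(rng.random() < config.validated_prob)
        if not echoed:
            validated = True  # keeps the pair retainable by construction
        in_mirdb = primary_is_mirdb or echoed
        in_morg = (not primary_is_mirdb) or echoed
        if in_mirdb:
            score = _round(rng.uniform(*config.mirdb_true_range))
            rows_mirdb.append((m, g, f"{score:.4f}"))
        if in_morg:
            morg_row(m, g, _round(rng.uniform(*config.mirsvr_true_range)))
            if rng.random() < config.duplicate_site_prob:
                # second predicted binding site for the same pair
                morg_row(m, g, _round(rng.uniform(*config.mirsvr_true_range)))
        if validated:
            support = _SUPPORT_TYPES[int(rng.random() < 0.3)]
            rows_mtb.append((m, g, support))

    # --- excluded miRNAs: single-predicted-database evidence only ----------
    for m in excluded_up + excluded_down:
        in_mirdb = bool(rng.random() < 0.5)
        n_rec = int(rng.integers(1, 3))
        targets = rng.choice(genes, size=n_rec, replace=False)
        for g in targets:
            g = str(g)
            if in_mirdb:
                score = _round(rng.uniform(*config.mirdb_true_range))
                rows_mirdb.append((m, g, f"{score:.4f}"))
            else:
                morg_row(m, g, _round(rng.uniform(*config.mirsvr_true_range)))

    # --- decoys -------------------------------------------------------------
    n_decoys = int(round(config.decoy_rate * len(true_pairs)))
    passing_decoy_pairs: set[tuple[str, str]] = set()
    for db in ("mirdb", "morg"):
        injected_boundary = False
        made = 0
        while made < n_decoys:
            m = str(rng.choice(active))
            g = str(rng.choice(genes))
            if (m, g) in true_pairs:
                continue
            failing = bool(rng.random() < 0.5)
            if not failing:
                if (m, g) in passing_decoy_pairs:
                    continue  # never passing in both predicted databases
                passing_decoy_pairs.add((m, g))
            if db == "mirdb":
                if failing:
                    score = (
                        config.mirdb_fail_range[1]  # exact removal boundary
                        if not injected_boundary
                        else _round(rng.uniform(*config.mirdb_fail_range))
                    )
                    injected_boundary = True
                else:
                    score = _round(rng.uniform(*config.mirdb_true_range))
                rows_mirdb.append((m, g, f"{score:.4f}"))
            else:
                if failing:
                    score = (
                        -1.2  # exact removal boundary
                        if not injected_boundary
                        else _round(rng.uniform(*config.mirsvr_fail_range))
                    )
                    injected_boundary = True
                else:
                    score = _round(rng.uniform(*config.mirsvr_true_range))
                morg_row(m, g, score)
            made += 1

    # --- GO annotation ------------------------------------------------------
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_terms)]
    planted_terms = set(
        rng.choice(terms, size=config.planted_term_count, replace=False).tolist()
    )
    target_genes = {g for _, g in true_pairs}
    annotation: list[tuple[str, str, str]] = []
    for g in genes:
        for t in terms:
            if t in planted_terms:
                rate = (
                    config.planted_term_effect
                    if g in target_genes
                    else config.background_term_rate
                )
            else:
                rate = config.background_term_rate
            if rng.random() < rate:
                annotation.append((g, t, f"synthetic process {int(t.split(':')[1])}"))

    file_rows = {
        "mirdb.tsv": sorted(rows_mirdb),
        "microrna_org_conserved.tsv": sorted(rows_morg_cons),
        "microrna_org_nonconserved.tsv": sorted(rows_morg_noncons),
        "mirtarbase.tsv": sorted(rows_mtb),
        "expression.tsv": [(e.mirna_id, e.direction.value) for e in expressions],
        "annotation.tsv": annotation,
    }
    return GroundTruth(
        expressions=expressions,
        true_interactions=true_pairs,
        planted_hubs=hubs,
        excluded_up=excluded_up,
        excluded_down=excluded_down,
        planted_terms=planted_terms,
        target_genes=target_genes,
        annotation_pairs=annotation,
        file_rows=file_rows,
    )


_HEADERS = {
    "mirdb.tsv": ("mirna_id", "gene_symbol", "target_score"),
    "microrna_org_conserved.tsv": ("mirna_id", "gene_symbol", "mirsvr_score"),
    "microrna_org_nonconserved.tsv": ("mirna_id", "gene_symbol", "mirsvr_score"),
    "mirtarbase.tsv": ("mirna_id", "gene_symbol", "support_type"),
    "expression.tsv": ("mirna_id", "direction"),
    "annotation.tsv": ("gene_id", "term_id", "term_name"),
}


def emit_files(
    truth: GroundTruth, config: GeneratorConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write all input files plus truth.json and a manifest; return paths.

    Output is byte-identical for identical (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    counts: list[tuple[str, int]] = []
    for name, rows in truth.file_rows.items():
        path = out / name
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(_HEADERS[name]) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        manifest[name] = path
        counts.append((name, len(rows)))

    truth_path = out / "truth.json"
    with truth_path.open("w", encoding="utf-8") as fh:
        json.dump(
            {
                "planted_hubs": sorted(truth.planted_hubs),
                "excluded_up": truth.excluded_up,
                "excluded_down": truth.excluded_down,
                "planted_terms": sorted(truth.planted_terms),
                "target_genes": sorted(truth.target_genes),
                "true_interactions": sorted(map(list, truth.true_interactions)),
                "config": asdict(config),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    manifest["truth.json"] = truth_path

    manifest_path = out / "manifest.tsv"
    with manifest_path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("file\trows\n")
        for name, n in counts:
            fh.write(f"{name}\t{n}\n")
    manifest["manifest.tsv"] = manifest_path
    return manifest
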