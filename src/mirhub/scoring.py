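"""Quality filtering, evidence collation and compound interaction scoring.

The procedure integrates three sources of miRNA-target evidence. Records
from the predicted databases are first screened by their native quality
scores: miRDB records survive only with target score strictly above 80.0
(scores <= 80.0 are removed) and microRNA.org records only with mirSVR
score strictly below -1.2 (scores >= -1.2 are removed). Validated records
carry no comparable score and bypass the filter.

Surviving records are collated per (miRNA, gene) pair and the pair receives
a *compound interaction score*: 0.5 points for each predicted database
contributing at least one surviving record (counted once per database, not
per binding site) plus 1 point for validated support. Pairs are retained
for network analysis iff the score is >= 1, which is exactly the rule that
discards interactions supported by a single predicted database and nothing
else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ingest import DbClass, DbName, InteractionRecord

__all__ = [
    "ScoringConfig",
    "EvidenceSet",
    "ScoredInteraction",
    "apply_quality_filter",
    "collate_evidence",
    "compound_score",
    "retain_interactions",
    "score_interactions",
    "write_scored_table",
]

PREDICTED_DBS = frozenset({DbName.MIRDB, DbName.MICRORNA_ORG})


@dataclass(frozen=True)
class ScoringConfig:
    """All numeric constants of the filtering/scoring/hub procedure.

    Defaults are the published procedure: miRDB records with target score
    <= 80.0 and microRNA.org records with mirSVR score >= -1.2 are removed
    (both bounds exclusive for *kept* records); each predicted database is
    worth 0.5 points and validated support 1 point; pairs scoring >= 1 are
    retained; mRNAs with at least 4 network interactions are hubs.
    """

    mirdb_min_exclusive: float = 80.0
    mirsvr_max_exclusive: float = -1.2
    points_per_predicted_db: float = 0.5
    points_validated: float = 1.0
    retention_min_score: float = 1.0
    hub_min_degree: int = 4

    def __post_init__(self) -> None:
        if self.points_per_predicted_db <= 0 or self.points_validated <= 0:
            raise ValueError("point values must be positive")
        if self.retention_min_score <= self.points_per_predicted_db:
            # otherwise a single predicted database would suffice, which the
            # retention rule exists to prevent
            raise ValueError(
                "retention_min_score must exceed points_per_predicted_db"
            )
        if self.hub_min_degree < 1:
            raise ValueError("hub_min_degree must be >= 1")

    @property
    def max_compound_score(self) -> float:
        return 2 * self.points_per_predicted_db + self.points_validated


@dataclass(frozen=True)
class EvidenceSet:
    """Database membership of one deduplicated (miRNA, gene) pair."""

    mirna_id: str
    gene_id: str
    dbs_present: frozenset[DbName]
    best_scores: dict[DbName, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.dbs_present:
            raise ValueError("dbs_present must be non-empty")
        extra = set(self.best_scores) - (set(self.dbs_present) & PREDICTED_DBS)
        if extra:
            raise ValueError(f"best_scores keys not in predicted membership: {extra}")


@dataclass(frozen=True)
class ScoredInteraction:
    mirna_id: str
    gene_id: str
    evidence: EvidenceSet
    compound_score: float
    retained: bool


def apply_quality_filter(
    records: Iterable[InteractionRecord], config: ScoringConfig | None = None
) -> list[InteractionRecord]:
    """Remove predicted records failing their database's quality threshold.

    Keeps miRDB records with score > ``mirdb_min_exclusive``, microRNA.org
    records with score < ``mirsvr_max_exclusive``, and every validated
    record. Order-preserving and idempotent; boundary scores are removed.
    """
    config = config or ScoringConfig()
    out: list[InteractionRecord] = []
    for rec in records:
        if rec.db_class is DbClass.VALIDATED:
            out.append(rec)
        elif rec.db_name is DbName.MIRDB:
            if rec.score is not None and rec.score > config.mirdb_min_exclusive:
                out.append(rec)
        elif rec.db_name is DbName.MICRORNA_ORG:
            if rec.score is not None and rec.score < config.mirsvr_max_exclusive:
                out.append(rec)
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown predicted database {rec.db_name}")
    return out


def collate_evidence(records: Iterable[InteractionRecord]) -> list[EvidenceSet]:
    """Group quality-filtered records into one EvidenceSet per pair.

    ``dbs_present`` is the set of databases contributing at least one
    surviving record; multiple binding-site rows from one database count
    once. Output is sorted by (mirna_id, gene_id).
    """
    dbs: dict[tuple[str, str], set[DbName]] = {}
    best: dict[tuple[str, str], dict[DbName, float]] = {}
    for rec in records:
        key = (rec.mirna_id, rec.gene_id)
        dbs.setdefault(key, set()).add(rec.db_name)
        if rec.db_name in PREDICTED_DBS and rec.score is not None:
            slot = best.setdefault(key, {})
            if rec.db_name not in slot:
                slot[rec.db_name] = rec.score
            elif rec.db_name is DbName.MIRDB:
                slot[rec.db_name] = max(slot[rec.db_name], rec.score)
            else:
                slot[rec.db_name] = min(slot[rec.db_name], rec.score)
    return [
        EvidenceSet(m, g, frozenset(dbs[(m, g)]), best.get((m, g), {}))
        for m, g in sorted(dbs)
    ]


def compound_score(evidence: EvidenceSet, config: ScoringConfig | None = None) -> float:
    """Evidence score of a pair: 0.5 per predicted database, 1 if validated."""
    config = config or ScoringConfig()
    n_pred = len(evidence.dbs_present & PREDICTED_DBS)
    validated = DbName.MIRTARBASE in evidence.dbs_present
    return (
        config.points_per_predicted_db * n_pred
        + config.points_validated * validated
    )


def retain_interactions(
    evidence_sets: Iterable[EvidenceSet], config: ScoringConfig | None = None
) -> list[ScoredInteraction]:
    """Score every pair and flag those meeting the retention threshold.

    Retention uses an exact >= comparison: compound scores are sums of the
    configured point constants (halves by default, exactly representable),
    so no epsilon is needed.
    """
    config = config or ScoringConfig()
    out: list[ScoredInteraction] = []
    for ev in evidence_sets:
        score = compound_score(ev, config)
        out.append(
            ScoredInteraction(
                ev.mirna_id, ev.gene_id, ev, score, score >= config.retention_min_score
            )
        )
    return out


def score_interactions(
    records: Iterable[InteractionRecord], config: ScoringConfig | None = None
) -> list[ScoredInteraction]:
    """Full scoring stage: quality filter -> collate -> score & retain."""
    config = config or ScoringConfig()
    return retain_interactions(
        collate_evidence(apply_quality_filter(records, config)), config
    )


def write_scored_table(
    scored: Sequence[ScoredInteraction], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna_id", "gene_id", "dbs_present", "compound_score", "retained"])
        for s in scored:
            writer.writerow(
                [
                    s.mirna_id,
                    s.gene_id,
                    ";".join(sorted(db.value for db in s.evidence.dbs_present)),
                    f"{s.compound_score:g}",
                    str(s.retained).lower(),
                ]
            )
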