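"""Readers for expression tables and interaction-database files.

Three historical miRNA-target sources are supported through configurable
column *dialects*: two predicted databases carrying a per-record confidence
score (a 0-100 target score for miRDB, a negative mirSVR downregulation
score for microRNA.org) and one curated database of experimentally
validated interactions (miRTarBase) that carries no comparable score.
Every row is mapped onto a uniform :class:`InteractionRecord` with
normalized miRNA and gene identifiers so records can be joined across
sources downstream.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "DbName",
    "DbClass",
    "Direction",
    "MirnaExpression",
    "DbDialect",
    "InteractionRecord",
    "ParseReport",
    "ParseError",
    "DEFAULT_DIALECTS",
    "normalize_mirna_id",
    "normalize_gene_id",
    "read_expression_table",
    "read_interaction_db",
    "write_interaction_db",
    "read_gene_map",
    "load_dialects",
    "write_parse_reports",
]


class DbName(str, Enum):
    """Identity of an interaction source."""

    MIRDB = "mirdb"
    MICRORNA_ORG = "microrna_org"
    MIRTARBASE = "mirtarbase"


class DbClass(str, Enum):
    PREDICTED = "predicted"
    VALIDATED = "validated"


#: db_name -> db_class is fixed by the study design.
DB_CLASS_OF: Mapping[DbName, DbClass] = {
    DbName.MIRDB: DbClass.PREDICTED,
    DbName.MICRORNA_ORG: DbClass.PREDICTED,
    DbName.MIRTARBASE: DbClass.VALIDATED,
}


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True, order=True)
class MirnaExpression:
    """One differentially expressed miRNA with its regulation direction."""

    mirna_id: str
    direction: Direction

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise ValueError("mirna_id must be non-empty")


@dataclass
class DbDialect:
    """Column layout of one database file.

    ``column_map`` maps the semantic fields ``mirna``, ``gene`` and (for
    predicted sources) ``score`` to 0-based column indices.
    """

    db_name: DbName
    column_map: Mapping[str, int]
    header_rows: int = 1
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        self.db_name = DbName(self.db_name)
        for key in ("mirna", "gene"):
            if key not in self.column_map:
                raise ValueError(f"column_map must define {key!r}")
        if self.db_class is DbClass.PREDICTED and "score" not in self.column_map:
            raise ValueError(f"{self.db_name.value}: predicted dialect needs a score column")
        indices = list(self.column_map.values())
        if len(set(indices)) != len(indices):
            raise ValueError("column indices must be distinct")
        if self.header_rows < 0:
            raise ValueError("header_rows must be non-negative")
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")

    @property
    def db_class(self) -> DbClass:
        return DB_CLASS_OF[self.db_name]


@dataclass(frozen=True)
class InteractionRecord:
    """One (miRNA, target gene) assertion from a single database."""

    mirna_id: str
    gene_id: str
    db_name: DbName
    db_class: DbClass
    score: float | None = None
    gene_raw: str | None = None  # original spelling, for reporting only

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.gene_id:
            raise ValueError("mirna_id and gene_id must be non-empty")
        if self.db_class is DbClass.PREDICTED and (
            self.score is None or not _finite(self.score)
        ):
            raise ValueError("predicted records must carry a finite score")


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass
class ParseReport:
    """Per-file ingestion accounting.

    ``rows_read`` counts non-empty data rows; ``rows_kept`` the records
    returned. rows_read = rows_kept + rows_skipped + duplicates_collapsed
    + species_dropped.
    """

    file: str
    rows_read: int = 0
    rows_kept: int = 0
    rows_skipped: int = 0
    duplicates_collapsed: int = 0
    species_dropped: int = 0
    malformed_scores: int = 0


_SPECIES_TOKEN = re.compile(r"^[a-z]{3,4}$")
_UNPREFIXED_HEAD = {"mir", "let"}


def normalize_mirna_id(raw: str, species_prefix: str = "rno") -> str:
    """Canonicalize a miRNA name.

    Lowercases, strips all whitespace and prepends the species prefix when
    the name carries none. A leading 3-4 letter token other than ``mir`` or
    ``let`` is treated as an existing species prefix and left alone (so a
    foreign-species record keeps its identity and can be filtered later).
    Arm suffixes (-5p/-3p) are preserved verbatim. Idempotent.
    """
    s = "".join(raw.split()).lower()
    if not s:
        raise ValueError("empty miRNA identifier")
    head = s.split("-", 1)[0]
    if head in _UNPREFIXED_HEAD or not _SPECIES_TOKEN.match(head):
        s = f"{species_prefix.lower()}-{s}"
    return s


def normalize_gene_id(raw: str) -> str:
    """Canonical gene symbol: surrounding whitespace stripped, uppercased."""
    s = raw.strip().upper()
    if not s:
        raise ValueError("empty gene identifier")
    return s


def read_expression_table(
    path: str | Path,
    delimiter: str = "\t",
    species_prefix: str = "rno",
) -> list[MirnaExpression]:
    """Read a differential-miRNA table (columns: mirna_id, direction).

    One header row is expected. Direction tokens are case-insensitive
    ``up``/``down``. Duplicate ids after normalization are an error.
    """
    path = Path(path)
    out: list[MirnaExpression] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 or not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            token = row[1].strip().lower()
            if token not in (Direction.UP.value, Direction.DOWN.value):
                raise ParseError(f"{path}:{lineno}: unparseable direction {row[1]!r}")
            mid = normalize_mirna_id(row[0], species_prefix)
            if mid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate miRNA id {mid!r}")
            seen.add(mid)
            out.append(MirnaExpression(mid, Direction(token)))
    return out


def read_gene_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Optional accession->symbol mapping (TSV, two columns, one header row).

    Keys and values are normalized via :func:`normalize_gene_id`.
    """
    mapping: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 or not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            mapping[normalize_gene_id(row[0])] = normalize_gene_id(row[1])
    return mapping


# Fraction of malformed-score rows above which ingestion aborts.
MALFORMED_ABORT_FRACTION = 0.01


def read_interaction_db(
    path: str | Path,
    dialect: DbDialect,
    species_prefix: str = "rno",
    gene_map: Mapping[str, str] | None = None,
) -> tuple[list[InteractionRecord], ParseReport]:
    """Read one database file into uniform records.

    Rows with a blank miRNA or gene are skipped and counted. Rows whose
    score fails to parse (predicted dialects) are skipped too, but if they
    exceed ``MALFORMED_ABORT_FRACTION`` of the data rows the whole read
    aborts. Records whose miRNA lacks the configured species prefix after
    normalization are dropped with a count (only the species-specific
    subset enters the analysis). Duplicate (miRNA, gene) rows within the
    file collapse to one record keeping the best score: maximum for miRDB
    target scores, minimum (most negative) for mirSVR scores.
    """
    path = Path(path)
    report = ParseReport(file=str(path))
    cmap = dialect.column_map
    need = max(cmap.values()) + 1
    prefix = species_prefix.lower() + "-"
    best: dict[tuple[str, str], InteractionRecord] = {}
    order: list[tuple[str, str]] = []
    malformed_rows: list[int] = []

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for lineno, row in enumerate(reader, start=1):
            if lineno <= dialect.header_rows:
                continue
            if not row or not any(cell.strip() for cell in row):
                continue
            report.rows_read += 1
            if len(row) < need:
                report.rows_skipped += 1
                continue
            raw_mirna = row[cmap["mirna"]].strip()
            raw_gene = row[cmap["gene"]].strip()
            if not raw_mirna or not raw_gene:
                report.rows_skipped += 1
                continue
            score: float | None = None
            if dialect.db_class is DbClass.PREDICTED:
                try:
                    score = float(row[cmap["score"]])
                except (ValueError, IndexError):
                    report.rows_skipped += 1
                    report.malformed_scores += 1
                    malformed_rows.append(lineno)
                    continue
                if not _finite(score):
                    report.rows_skipped += 1
                    report.malformed_scores += 1
                    malformed_rows.append(lineno)
                    continue
            mirna = normalize_mirna_id(raw_mirna, species_prefix)
            if not mirna.startswith(prefix):
                report.species_dropped += 1
                continue
            gene = normalize_gene_id(raw_gene)
            if gene_map is not None:
                gene = gene_map.get(gene, gene)
            key = (mirna, gene)
            rec = InteractionRecord(
                mirna, gene, dialect.db_name, dialect.db_class, score, raw_gene
            )
            if key not in best:
                best[key] = rec
                order.append(key)
            else:
                report.duplicates_collapsed += 1
                if score is not None:
                    prev = best[key].score
                    assert prev is not None
                    keep_new = (
                        score > prev
                        if dialect.db_name is DbName.MIRDB
                        else score < prev
                    )
                    if keep_new:
                        best[key] = rec

    if report.rows_read and (
        report.malformed_scores / report.rows_read > MALFORMED_ABORT_FRACTION
    ):
        raise ParseError(
            f"{path}: {report.malformed_scores}/{report.rows_read} rows have "
            f"malformed scores (first at line {malformed_rows[0]})"
        )
    records = [best[k] for k in order]
    report.rows_kept = len(records)
    return records, report


def write_interaction_db(
    records: Sequence[InteractionRecord], path: str | Path, dialect: DbDialect
) -> None:
    """Write records back out in a dialect's layout (inverse of reading)."""
    cmap = dialect.column_map
    width = max(cmap.values()) + 1
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        header = [""] * width
        for name, idx in cmap.items():
            header[idx] = name
        for _ in range(dialect.header_rows):
            writer.writerow(header)
        for rec in records:
            row = [""] * width
            row[cmap["mirna"]] = rec.mirna_id
            row[cmap["gene"]] = rec.gene_id
            if "score" in cmap and rec.score is not None:
                row[cmap["score"]] = repr(rec.score)
            writer.writerow(row)


#: The four input files of the study and their layouts as this package
#: emits them (synthetic module) and reads them by default.
DEFAULT_DIALECTS: dict[str, DbDialect] = {
    "mirdb": DbDialect(DbName.MIRDB, {"mirna": 0, "gene": 1, "score": 2}),
    "microrna_org_conserved": DbDialect(
        DbName.MICRORNA_ORG, {"mirna": 0, "gene": 1, "score": 2}
    ),
    "microrna_org_nonconserved": DbDialect(
        DbName.MICRORNA_ORG, {"mirna": 0, "gene": 1, "score": 2}
    ),
    "mirtarbase": DbDialect(DbName.MIRTARBASE, {"mirna": 0, "gene": 1}),
}


def load_dialects(path: str | Path) -> dict[str, DbDialect]:
    """Load dialect definitions from a YAML/JSON config.

    Expected keys: mirdb, microrna_org_conserved, microrna_org_nonconserved,
    mirtarbase; each entry may define db_name, columns, header_rows and
    delimiter, with fallbacks to the defaults above.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out: dict[str, DbDialect] = {}
    for key, default in DEFAULT_DIALECTS.items():
        entry = (data or {}).get(key, {}) or {}
        out[key] = DbDialect(
            db_name=DbName(entry.get("db_name", default.db_name.value)),
            column_map=entry.get("columns", dict(default.column_map)),
            header_rows=entry.get("header_rows", default.header_rows),
            delimiter=entry.get("delimiter", default.delimiter),
        )
    return out


def write_parse_reports(reports: Iterable[ParseReport], path: str | Path) -> None:
    cols = [
        "file",
        "rows_read",
        "rows_kept",
        "rows_skipped",
        "duplicates_collapsed",
        "species_dropped",
    ]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in reports:
            writer.writerow([getattr(r, c) for c in cols])
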