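"""Gene-ontology over-representation analysis with Bonferroni correction.

Given a study set of genes and a flat gene -> GO-term annotation table, each
term is tested for over-representation against the annotated background.
The default statistic is the one-sided hypergeometric (Fisher) tail
P(X >= k) for X ~ Hypergeometric(N, K, n), where N is the background size,
K the background genes carrying the term, n the annotated study-set size
and k the study genes carrying the term. A binomial approximation
P(X >= k), X ~ Binomial(n, K/N), is available as well, since historical
releases of the PANTHER tool used it. Raw p-values are Bonferroni-adjusted
by the number of terms actually tested.

No DAG propagation is performed: annotations are taken as given, so
pre-propagated annotation files are the caller's responsibility.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .ingest import ParseError, normalize_gene_id

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "EnrichMethod",
    "read_annotation",
    "enrich",
    "bonferroni",
    "write_enrichment_table",
    "significance_stars",
]

logger = logging.getLogger(__name__)


class EnrichMethod(str, Enum):
    HYPERGEOMETRIC = "hypergeometric"
    BINOMIAL = "binomial"


@dataclass
class AnnotationMap:
    """Bidirectional gene<->term association with the annotation background."""

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    @property
    def background(self) -> set[str]:
        return set(self.gene_to_terms)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], term_names: dict[str, str] | None = None
    ) -> "AnnotationMap":
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        return cls(g2t, t2g, term_names or {})


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study genes with the term
    n: int  # annotated study-set size
    K: int  # background genes with the term
    N: int  # background size
    p_raw: float
    p_adj: float
    enriched: bool


def read_annotation(path: str | Path, delimiter: str = "\t") -> AnnotationMap:
    """Read a TSV of gene->term associations (one per row, one header row).

    Columns: gene_id, term_id and an optional term_name. Duplicate
    associations collapse; rows with missing fields are skipped with a
    logged count; gene ids are normalized to canonical symbols.
    """
    pairs: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    skipped = 0
    rows = 0
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 or not row or not any(cell.strip() for cell in row):
                continue
            rows += 1
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                skipped += 1
                continue
            gene = normalize_gene_id(row[0])
            term = row[1].strip()
            pairs.append((gene, term))
            if len(row) > 2 and row[2].strip():
                names[term] = row[2].strip()
    if rows == 0:
        raise ParseError(f"{path}: annotation file has no data rows")
    if skipped:
        logger.warning("%s: %d annotation rows skipped (missing fields)", path, skipped)
    return AnnotationMap.from_pairs(pairs, names)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Elementwise min(1, p*m); m must be at least the number of tests."""
    if m < len(p_values) or m < 1:
        raise ValueError("m must be a positive integer >= number of p-values")
    out = []
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append(min(1.0, p * m))
    return out


def _upper_tail(k: int, n: int, K: int, N: int, method: EnrichMethod) -> float:
    if method is EnrichMethod.HYPERGEOMETRIC:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    else:
        p = float(stats.binom.sf(k - 1, n, K / N))
    # survival functions can round to tiny negatives / above-1 values
    return min(1.0, max(p, 0.0)) or 5e-324


def enrich(
    study_set: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
    method: EnrichMethod | str = EnrichMethod.HYPERGEOMETRIC,
) -> list[EnrichmentResult]:
    """Over-representation test of every annotated term in the study set.

    Study genes absent from the annotation background are excluded from n
    (and logged). One result per term present in the background; the
    Bonferroni multiplier m is the number of terms tested. Results are
    sorted by adjusted p ascending, term_id ascending on ties.
    """
    method = EnrichMethod(method)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    background = annotation.background
    study = set(study_set)
    effective = study & background
    if not effective:
        raise ValueError("study set has no genes in the annotation background")
    dropped = len(study) - len(effective)
    if dropped:
        logger.info("%d study genes absent from background excluded", dropped)
    N, n = len(background), len(effective)
    terms = sorted(t for t, genes in annotation.term_to_genes.items() if genes)
    m = len(terms)
    results = []
    for term in terms:
        K = len(annotation.term_to_genes[term])
        k = len(annotation.term_to_genes[term] & effective)
        p_raw = _upper_tail(k, n, K, N, method)
        p_adj = min(1.0, p_raw * m)
        results.append(
            EnrichmentResult(
                term,
                annotation.term_names.get(term, ""),
                k,
                n,
                K,
                N,
                p_raw,
                p_adj,
                p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return results


def significance_stars(p_adj: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["term_id", "term_name", "k", "n", "K", "N", "p_raw", "p_adj", "enriched", "stars"]
        )
        for r in results:
            writer.writerow(
                [
                    r.term_id,
                    r.term_name,
                    r.k,
                    r.n,
                    r.K,
                    r.N,
                    f"{r.p_raw:.6g}",
                    f"{r.p_adj:.6g}",
                    str(r.enriched).lower(),
                    significance_stars(r.p_adj),
                ]
            )
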