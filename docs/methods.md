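# Methods

## Evidence model

The unit of evidence is a database record asserting that a miRNA targets a
gene. Records come from two *predicted* sources with native quality scores
and one *validated* source without:

| source | class | native score | kept iff |
|---|---|---|---|
| miRDB | predicted | target score, 0–100, higher = stronger | score > 80.0 |
| microRNA.org | predicted | mirSVR score, negative = stronger repression | score < −1.2 |
| miRTarBase | validated | — | always |

Both thresholds are exclusive for kept records: the boundary values 80.0
and −1.2 are removed. microRNA.org ships as two bundles (conserved and
non-conserved miRNAs); both are read and treated as one database.
Within one file, duplicate (miRNA, gene) rows — e.g. one row per binding
site — collapse to a single record keeping the best score (maximum target
score, minimum mirSVR score); across the conserved/non-conserved bundles
the same pair may legitimately appear twice and is merged at collation.

After quality filtering, each distinct (miRNA, gene) pair receives a
compound score: 0.5 points per predicted database contributing ≥ 1
surviving record plus 1 point for validated support, so the score lies in
{0.5, 1.0, 1.5, 2.0}. Counting per database rather than per row is forced
by consistency: per-row counting would let two binding sites in a single
predicted database reach the retention threshold, contradicting the rule
that single-predicted-database interactions are excluded. Retention is the
exact comparison `score >= 1.0`; since all point values are small dyadic
rationals, the sums are exactly representable and no epsilon is needed.
A pair supported by one predicted plus the validated database (1.5) is
retained by the formula, the same as validated-only (1.0); we implement
the formula as stated rather than special-casing validated evidence.

## Identifier normalization

miRNA names are lowercased, whitespace-stripped, and given the configured
species prefix (default `rno`) when they carry none; an existing 3–4
letter species token is preserved, and records whose prefix differs from
the configured species are dropped with a count (the analysis is
species-specific). Arm suffixes (`-5p`/`-3p`) are preserved verbatim; the
normalizer is idempotent. Gene symbols are uppercased for joining, with
the original spelling retained on the record for reporting. Real miRDB
exports carry RefSeq accessions rather than symbols; an optional
accession→symbol mapping file is applied at read time so the join logic
stays namespace-agnostic. How the original analyses reconciled gene
namespaces across databases is not documented anywhere we could find, so
the mapping mechanism is this package's own construction.

A file aborts ingestion if more than 1 % of its data rows carry
unparseable scores; isolated malformed rows are skipped and counted in the
parse report.

## Network and hubs

The bipartite graph contains the differentially expressed miRNAs with ≥ 1
retained interaction (direction-labelled), their target genes, and one
unweighted edge per retained pair (the compound score and database
membership ride along as attributes; degree ignores them). Differential
miRNAs with no surviving interaction are reported separately rather than
added as isolated nodes. A hub is a gene whose degree reaches
`hub_min_degree` (default 4). Two degree modes exist because the two
natural definitions — all regulators versus upregulated regulators only —
are both in use and genuinely differ on mixed-direction genes; the default
is `total`, and the hub table reports `degree_up`/`degree_down` so either
can be audited. Hub ranking sorts by the mode's degree descending with
lexicographic gene-id tie-break, so output order is total and stable.

The Venn partition classifies each target gene by the direction set of its
regulators. `union_total` is the distinct-gene count; the report also
carries `naive_sum` (up-total + down-total), which double-counts shared
genes, because summaries in the field sometimes add the two circles.

## Over-representation test

For a study set reduced to the annotated background (N genes), a term
carried by K background genes and k of the n effective study genes gets
the one-sided upper-tail p-value P(X ≥ k) under X ~ Hypergeom(N, K, n)
(`scipy.stats.hypergeom.sf`). The hosted GO tools this replaces did not
document their statistic at the time; the hypergeometric (Fisher) test is
the modern default and a binomial alternative P(X ≥ k), X ~ Binom(n, K/N)
is provided because historical PANTHER releases used it. Bonferroni
correction multiplies by m = number of terms tested (terms with K ≥ 1),
not the full ontology size — the conservative defensible choice given that
only tested hypotheses exist after the analysis. Annotations are taken as
a flat gene→term table with no DAG propagation; callers wanting ancestor
closure must pre-propagate. The background defaults to all annotated
genes; study genes outside it are excluded from n and logged. p-values are
floored at the smallest positive double so the (0, 1] invariant survives
underflow in extreme enrichments.

## Synthetic study generator

The generator emulates the shape of a typical differential-miRNA study: 47
up- and 10 downregulated miRNAs of which 4 and 2 are planted to fail the
inclusion criteria, 500 genes of which 11 are hubs with 5 true regulators
each, 70 % probability that a true interaction is echoed in the second
predicted database, a 30 % validated fraction, 30 % decoy rate, and 40 GO
terms of which 3 are planted enriched among target genes (carry
probability 0.8 on targets vs 0.1 background). Score distributions sit
strictly on the passing/failing sides of the filter boundaries, and
failing decoys include the exact boundary values (80.0, −1.2) so boundary
behavior is exercised by construction. Scores are rounded to 4 decimals at
generation time so the written text round-trips to the identical float.

Three guarantees are structural, not probabilistic: a true interaction not
echoed into the second predicted database is forced into the validated
database (so the true set and the retained set coincide); decoys carry
either failing scores or passing single-database membership, and no pair
gets passing decoys in both predicted databases (so no decoy is ever
retained); non-hub degrees are drawn from {0,…,3}, below the hub
threshold (so hub recovery is exact, noise or not). A non-excluded miRNA
that draws zero targets is attached to a gene with spare sub-threshold
capacity, so the excluded-miRNA report recovers exactly the planted sets.

What the generator does **not** emulate: sequence-level seed matching and
binding energetics, realistic score distributions or database biases,
expression dynamics, and correlated annotations (real GO terms are
hierarchically nested; synthetic terms are independent). Passing
closed-loop tests therefore demonstrates that the *rules* are implemented
correctly and recover planted structure, not that the procedure's
biological precision on real databases is high.

## Numerical and design choices

- All analysis stages are deterministic; randomness is confined to the
  generator (`numpy.random.default_rng(seed)`), and emitted files are
  byte-identical for a fixed config.
- Problem sizes in the test suite (≤ 200-record scoring oracles,
  exhaustive hypergeometric enumeration at N ≤ 25, a 1000-replicate null
  calibration on a 2000-gene background, 20-seed enrichment power) were
  chosen so each suite completes in seconds while the oracles stay
  exhaustive or well-powered.
- The null-calibration fixture uses large terms (K = 150–250 on N = 2000,
  n = 200) because the hypergeometric test is conservative under
  discreteness; with small K the attainable level sits well below nominal
  and a two-sided band around 0.05 would be the wrong check.
- Empty retained sets, empty networks and unannotated study sets complete
  with warnings and empty outputs rather than errors; a missing input file
  or dialect mismatch fails the run.

## Known limitations

- Gene namespace reconciliation is delegated to the optional mapping file;
  no online lookup is performed.
- No GO DAG handling, term–term relationships, or GO-slim mapping.
- Hubs are degree-based only; no centrality measures, layout, or pathway
  topology.
- The generator's decoy model is pair-level; it does not simulate
  systematically biased databases (e.g. one source over-predicting for a
  gene family).
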