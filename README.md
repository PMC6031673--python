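# mirhub

Unbiased miRNA-target prediction by multi-database evidence integration,
bipartite network hub analysis and GO over-representation testing.

## The problem

A differential-expression experiment yields a list of up- and downregulated
miRNAs, but any single target-prediction database is noisy. `mirhub`
implements a conservative integration procedure over two predicted sources
(miRDB target scores, microRNA.org mirSVR scores) and one experimentally
validated source (miRTarBase):

1. **Quality filter.** miRDB records with target score ≤ 80.0 and
   microRNA.org records with mirSVR score ≥ −1.2 are removed (higher miRDB
   scores and more negative mirSVR scores mean stronger predictions);
   validated records have no comparable score and pass unfiltered.
2. **Compound evidence score.** For each (miRNA, gene) pair,

   *S* = 0.5 · #{predicted databases with a surviving record} + 1 · [validated]

   Each database counts once, regardless of how many binding-site rows it
   lists. Pairs are **retained** iff *S* ≥ 1 — equivalently, an interaction
   supported by only one predicted database and nothing else is discarded.
3. **Bipartite network & hubs.** Retained interactions of the
   differentially expressed miRNAs form a bipartite graph (miRNA nodes
   carry their regulation direction). Target mRNAs with at least 4
   interactions are *hubs*; the degree can count all regulators (`total`)
   or only upregulated ones (`up_only`). Target genes are partitioned by a
   Venn classification into up-only / down-only / both.
4. **GO over-representation.** Any target set (up-targets, down-targets,
   common targets, hubs) is tested against a flat gene→GO annotation
   background with the one-sided hypergeometric test
   p = P(X ≥ k), X ~ Hypergeom(N, K, n) (a binomial variant is available),
   Bonferroni-corrected by the number of terms tested.

A seeded synthetic-data generator (`mirhub.synthetic`) produces all inputs
with planted ground truth — hub genes, miRNAs destined for exclusion, and
enriched GO terms — so the whole pipeline is testable end to end without
downloading any database.

## Worked example

```bash
mirhub simulate --seed 1 --out demo      # synthetic study + run config
mirhub run --config demo/config.yaml --out demo/out
```

prints

```
retained 457/605 pairs; network 51 miRNAs x 246 genes; 11 hubs; 10 enriched terms
```

Of 605 distinct (miRNA, gene) pairs that survive the quality filter, 457
score ≥ 1 and enter the network. 51 of the 57 differential miRNAs keep at
least one retained interaction (the planted 4 up + 2 down drop out, listed
in `excluded_mirnas.tsv`); the 11 planted hub genes are exactly the genes
flagged `is_hub` in `hub_table.tsv`:

```
gene_id	degree_total	degree_up	degree_down	is_hub
GENE0014	5	5	0	True
GENE0043	5	5	0	True
...
```

`venn_counts.tsv` partitions the 246 target genes by regulator direction
(`naive_sum` double-counts the shared genes, for comparability with
reports that sum the two circles):

```
up_only	down_only	both	union_total	naive_sum
179	24	43	246	289
```

and `enrichment_up_targets.tsv` shows the planted GO terms at the top:

```
term_id	term_name	k	n	K	N	p_raw	p_adj	enriched	stars
GO:0000037	synthetic process 37	187	222	236	498	3.76e-53	1.51e-51	true	***
```

Here k of the n annotated study genes carry the term, K of the N
background genes do; `p_adj` is Bonferroni-corrected; stars mark
p < 0.05 / 0.01 / 0.001. Other outputs: `network.graphml` (for Cytoscape
or any GraphML consumer), `edge_list.tsv`, `scored_interactions.tsv`,
`parse_report.tsv` and a machine-readable `report.json`. Stage-level
subcommands (`ingest`, `score`, `network`, `hubs`, `enrich`) run the
pipeline up to the corresponding point; real database exports are
consumed by pointing the config's `inputs` at your files and, if their
column layouts differ, overriding the `dialects` section.

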