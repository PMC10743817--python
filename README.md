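# plgenes

Gene-level analytics for the genetics of pregnancy loss (miscarriage,
stillbirth, termination for fetal abnormality, and recurrent pregnancy
loss, RPL). The package is aimed at researchers who curate published
case reports of euploid pregnancy loss attributed to point mutations
and want to (a) summarize and stratify such a variant catalogue, (b)
characterize the implicated genes by evolutionary constraint and
expression pattern, (c) test the gene list for pathway
over-representation, and (d) nominate new candidate genes that share
the properties of the known ones.

## What it computes

**Catalogue analytics.** A catalogue is a list of case records
(gene, HGVS-like variant(s), parental origin, pregnancy outcome,
recurrence, study key); a compound-heterozygous pair reported for one
fetus is a single record with two variant strings. Summaries report
distinct genes and variants, genes reported by ≥ 2 independent studies,
genes with ≥ 2 distinct variants, and strata by recurrence (RPL vs
non-RPL) or by outcome. A literature-curated catalogue of the 18
multi-study pregnancy-loss genes (51 case records) ships with the
package (`plgenes.datasets.load_multistudy_catalogue()`).

**Constraint and expression profiles.** Per gene group: the median
LOEUF (loss-of-function observed/expected upper-bound fraction; lower =
more constrained), the proportions of pLI tolerance classes (tolerant
pLI ≤ 0.1, intolerant pLI ≥ 0.9), expression breadth (number of tissues
with ≥ 10 TPM) and the median of per-gene median TPM across tissues.

**Over-representation analysis.** For a query of *n* genes in a
universe of *N*, a set with *K* members and overlap *k* is scored with
the one-sided hypergeometric upper tail

P(X ≥ k) = Σ<sub>j≥k</sub> C(K, j) · C(N−K, n−j) / C(N, n),

with Benjamini–Hochberg step-up FDR adjustment within each collection.
A keyword classifier flags development-related terms ("development",
"morphogenesis", "formation") and splits a gene list into
development-annotated versus not.

**Candidate-gene cascade.** Thresholds are derived from the curated
seed genes — `loeuf_max` = median seed LOEUF, `tpm_min` = median over
seeds of per-gene median TPM — and the whole universe is filtered in
four stages: (1) LOEUF < `loeuf_max`; (2) median TPM ≥ `tpm_min`;
(3) ≥ 1 physical interaction with a seed gene; (4) membership in ≥ 1
enriched pathway (all significant sets, or the top-k). Seeds are
removed after stage 4 and the surviving candidates are split into
known Mendelian-disease genes and novel ones via a gene→disease map.

**Synthetic annotation worlds.** `plgenes.synthdata` generates a
self-consistent world (constraint table, expression matrix, PPI edge
list, GMT gene sets, disease map, seed catalogue) with planted
ground truth: candidate genes that pass every cascade stage and decoy
blocks that each fail exactly one stage, so the full pipeline is
testable end to end without any external downloads.

## Worked example

Summarize the packaged catalogue:

```
$ plg catalogue-stats src/plgenes/data/multistudy_pl_catalogue.tsv --stratify recurrence
records 51
variant_entries 60
distinct_variants 60
genes 18
multi_study_genes 18
multi_variant_genes 18
stratum:rpl      2 records, 2 genes, 3 distinct variants
stratum:non_rpl  49 records, 18 genes, 57 distinct variants
```

51 published cases over 18 genes, each gene reported by at least two
independent studies; two cases (in *FOXP3* and *RYR2*) were explicitly
recurrent-pregnancy-loss reports.

Simulate a synthetic world and run the cascade on it:

```
$ plg simulate --seed 11 --outdir world/
$ plg prioritize --config world/run.yaml --out-dir world/out
thresholds: loeuf_max=0.3487 tpm_min=24.16
stages: constraint=169 -> expression=116 -> ppi=66 -> pathway=16
candidates=10 (seed overlap 6; known 4, novel 6)
```

(`run.yaml` names the emitted catalogue/constraint/expression/network/
GMT/disease files.) The 18 synthetic seed genes give a LOEUF ceiling of
0.3487 and a TPM floor of 24.16; 169 of 2000 genes survive the
constraint filter, 116 the expression filter, 66 the interaction
filter and 16 the pathway filter. Removing the 6 surviving seeds
leaves the 10 planted candidates — 4 with a disease annotation
("known") and 6 without ("novel") — exactly the world's ground truth.

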