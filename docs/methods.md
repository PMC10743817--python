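# Methods

## Catalogue model and conventions

A catalogue record is one reported pregnancy-loss case. Identity
conventions, chosen once and used everywhere:

* **Case vs variant counting.** A compound-heterozygous pair printed as
  one case is one record with two variant strings. Because published
  tallies sometimes count cases and sometimes variants, summaries
  expose both `n_records` and `n_variant_entries`, plus
  `n_distinct_variants` (deduplicated). Distinct-variant identity is
  the transcript-stripped, whitespace-normalized variant string; the
  protein annotation is kept, so the same nucleotide change printed
  with different protein notations counts as distinct strings. This is
  deliberate: collapsing further would require HGVS normalization
  against transcript sequence, which is out of scope.
* **Multi-study genes** require ≥ 2 distinct non-empty study keys, not
  distinct cohorts within one publication.
* **Recurrence.** A record with outcome `rpl` is forced to
  `recurrent=True`; otherwise recurrence comes from its own column.
  In the recurrence stratification, unreported recurrence counts as
  `non_rpl` — the curated literature usually does not state it, and
  treating "not stated" as non-recurrent matches how such catalogues
  are tallied.
* **Outcome strata.** The outcome scheme must partition all records,
  so beyond the three groups used in the field's figures
  (miscarriage/stillbirth/fetal death, termination, and
  "fetal demise or termination") the scheme folds `rpl` records into
  the miscarriage group (RPL *is* recurrent miscarriage) and keeps
  `neonatal_death` as its own stratum.
* Unknown origin/outcome/recurrence tokens fail loudly with the row
  number; nothing is silently coerced.

## Resource handling

All joins are exact string joins on trimmed, uppercased symbols; an
optional alias TSV is applied at load time in every loader, so a
legacy symbol is mapped once and consistently. Genes missing from a
resource are excluded from analyses needing that resource and the
effective denominators are carried on the results (profiles record
`n_genes_with_constraint` / `n_genes_with_expression`; thresholds
record seed denominators). Missing pLI/LOEUF values are kept as
absent, never imputed. Duplicate constraint rows keep the lowest
LOEUF (the conservative, more-constrained estimate). Networks are
undirected, deduplicated, self-loops dropped with a logged count.

## Profiling

* pLI classes: tolerant pLI ≤ 0.1, intolerant pLI ≥ 0.9, intermediate
  otherwise. Boundaries are inclusive by default (the operative prose
  definition of the classes), with a `strict_boundaries` flag for the
  strict variant; for continuous pLI the boundary mass is negligible.
* Expression breadth: count of tissues with TPM ≥ threshold,
  threshold inclusive, default 10 TPM.
* Medians use the mean-of-central-pair convention for even-length
  samples (numpy's default), everywhere — group profiles and cascade
  thresholds alike.
* The all-genes expression background is dominated by unexpressed
  genes, and a "how many times higher" ratio depends on whether zeros
  enter the denominator median; profiles therefore report both
  `median_of_median_tpm` and a nonzero-only variant instead of
  choosing one.
* Group comparisons are descriptive (differences of medians against
  the first group); no inferential statistic is attached because none
  is defined for this design.

## Over-representation analysis

One-sided hypergeometric upper tail, computed through the survival
function for stability (verified in tests against brute-force
enumeration over every consistent configuration with N ≤ 30 at
relative error < 1e−9). BH step-up is implemented explicitly
(`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1) and cross-checked against
statsmodels in tests; adjusted values are clamped elementwise to be
≥ raw, removing sub-ulp floating-point undershoot. Correction runs
within each collection separately — GO BP/CC/MF and curated-pathway
collections are distinct test families. The universe defaults to the
genes annotated in the collection and can be overridden with an
explicit background (the cascade pipeline passes all genes with
constraint data). Reporting defaults: overlap ≥ 1, set size within
[5, 2000] — conventional ORA practice, all configurable.

Development-keyword classification is a case-insensitive substring
match of term names against "development", "morphogenesis",
"formation". Annotations are taken as supplied in the GMT; no
ontology-graph propagation is attempted, so a gene annotated only to a
descendant of a developmental term with a non-matching name will not
be flagged.

## Cascade

* Constraint filter is strict (LOEUF < `loeuf_max`); expression filter
  is inclusive (median TPM ≥ `tpm_min`). Both derive from "keep genes
  at least as constrained / at least as expressed as the typical seed
  gene"; both inequalities are fixed conventions, stated here rather
  than configurable per call.
* A gene passes the interaction stage iff it shares an edge with at
  least one seed other than itself; seed–seed edges therefore count
  for seeds, which is what lets seed genes survive to the final stage
  and be reported as the seed overlap before removal. A gene absent
  from the network fails the stage, as does a gene missing constraint
  or expression data at its stage (conservative; counts logged).
* Pathway stage: membership in the union of significant sets across
  all configured collections (mode `all_enriched`) or the top-k by
  (p_adjusted, p_raw, set_name); ties at rank k are all included so
  equally significant sets are never dropped arbitrarily, and the
  expansion is logged.
* Seeds are removed only after the pathway stage; candidate
  classification is known (≥ 1 disease-map entry) vs novel.
* The cascade is fully deterministic: set operations, explicit sort
  keys, no randomness.

## Synthetic worlds

The generator emulates the statistical structure the cascade assumes,
with planted ground truth:

* **Blocks.** 18 seed genes (default), 10 planted candidates, four
  decoy blocks of 50 genes each failing exactly one stage, and a
  background filling the 2000-gene universe. These defaults are the
  desk-scale study condition used by the test suite.
* **Constraint.** LOEUF is a two-component mixture: a constrained
  component (normal, mean 0.35, sd 0.12, truncated positive) for
  seeds, planted genes and non-constraint decoys, and an unconstrained
  component (mean 1.1, sd 0.25) for the constraint decoys and the
  background, truncated *above* the seed median — so background genes
  deterministically fail stage 1 and per-stage survivor sets are exact
  rather than probabilistic. pLI is a monotone decreasing logistic
  transform of LOEUF plus noise, clipped to [0, 1].
* **Expression.** Log-normal tissue profiles rescaled to an exact
  target median: seeds around 25 TPM; pass-blocks at 1.3–2.5× the seed
  median threshold; the expression-decoy block at 0.2–0.7×.
* **Network.** A seed ring (every seed adjacent to another seed),
  guaranteed seed edges for blocks that must pass the PPI stage,
  guaranteed *absence* of seed edges for the PPI-decoy block, plus
  Erdős–Rényi background edges (p = 0.002) that never connect a
  PPI-decoy to a seed.
* **Pathways.** One planted set containing the planted candidates,
  each seed with probability 0.9, the stage-1–3 decoys and some
  background; the remaining random sets draw members only from genes
  that already fail an earlier stage (never seeds, planted genes or
  pathway decoys). Consequently the planted set is the only set with
  any seed overlap, hence the only significant one — this is the
  design choice that makes planted recovery exact. Random set names
  carry development-style or neutral suffixes for the keyword
  classifier.
* **Disease map.** Planted genes are "known" with probability 0.5;
  seeds and background get entries at realistic rates (0.8 / 0.1).
* **Catalogue.** Records over the seed genes with configurable
  categorical outcome/origin distributions, a configurable
  multi-study fraction (forced distinct study keys), compound-het
  probability 0.15, or a fixed total record count for sampling tests.
* **Determinism.** One `numpy.random.Generator` stream from
  `rng_seed`; LOEUF/pLI rounded to 4 decimals and TPM to 3 at
  generation time so the in-memory world, the emitted files and
  re-loaded resources agree exactly and repeated runs are
  byte-identical. The generator recomputes its expected per-stage
  survivors from its own attribute arrays with one-line comparisons —
  an accounting independent of the cascade implementation.

**What passing on synthetic worlds does and does not show.** The
worlds have clean block structure, uncorrelated noise, no symbol
aliasing problems, no missing values and a single unambiguous enriched
pathway. Passing demonstrates that the pipeline's logic, thresholds
and bookkeeping are correct — not that real gnomAD/GTEx/BioGRID/MSigDB
resources would yield any particular candidate list; real resources
have correlated annotations, incomplete coverage and version-dependent
content, and runs against them are resource-version dependent by
nature.

## Problem sizes and numerical choices

Tests run on worlds of 400–2000 genes, 30 tissues, 15–40 gene sets;
the enrichment-power check uses 200 replicate 800-gene worlds; the
hypergeometric verification sweeps every consistent configuration up
to N = 30 (~24k tail probabilities). These sizes were chosen so the
whole suite completes in well under a minute while leaving every
combinatorial margin (decoy accounting, median parity, tie handling)
exercised. Degenerate inputs are rejected explicitly: empty gene
groups, empty effective queries, matrices without tissues, seed sets
without resource coverage, infeasible world configurations.

## Known limitations

* No HGVS validation or variant-level normalization; variant identity
  is string-based.
* No GO graph propagation before keyword matching.
* The cascade produces an unranked candidate set; no scoring or
  network diffusion beyond first-neighbor adjacency.
* Trimester-stratified comparisons are not implemented (gestational
  age is carried on records but rarely reported in sources).
* Catalogue curation itself (literature retrieval, ACMG
  classification) is manual and out of scope; the package starts from
  a curated table.
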