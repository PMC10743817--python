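"""Candidate-gene prioritization cascade.

Starting from the whole gene universe, four sequential filters keep the
genes that look like the literature-curated seed genes:

1. **constraint** — LOEUF strictly below the seed median (``loeuf_max``);
2. **expression** — per-gene median across-tissue TPM at or above the
   seed median of the same quantity (``tpm_min``);
3. **ppi** — at least one physical interaction with a seed gene;
4. **pathway** — membership in at least one enriched gene set (all
   significant sets, or the top-k most significant).

Seed genes themselves ride through the cascade and are removed only
after the pathway stage, so the overlap between survivors and seeds is
reported; the remaining candidates are split into known disease genes
and novel ones via the disease map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import EnrichmentResult, select_top_sets
from .resources import (
    ConstraintMap,
    DiseaseMap,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
)

logger = logging.getLogger(__name__)

ALL_ENRICHED = "all_enriched"
TOP_K = "top_k"

STAGE_LABELS = ("constraint", "expression", "ppi", "pathway")


@dataclass(frozen=True)
class ThresholdSet:
    """Filter thresholds derived from the seed genes.

    ``loeuf_max`` is the median LOEUF over seeds with constraint data;
    ``tpm_min`` the median over seeds of each seed's median across-tissue
    TPM.
    """

    loeuf_max: float
    tpm_min: float
    n_seeds_with_constraint: int = 0
    n_seeds_with_expression: int = 0


@dataclass(frozen=True)
class CascadeResult:
    """Per-stage surviving gene sets and the final candidate split."""

    thresholds: ThresholdSet
    stages: tuple[tuple[str, frozenset[str]], ...]
    pathway_mode: str
    selected_set_names: tuple[str, ...]
    seed_overlap: frozenset[str]
    candidates: frozenset[str]
    known_disease: frozenset[str]
    novel: frozenset[str]

    @property
    def stage_counts(self) -> dict[str, int]:
        return {label: len(genes) for label, genes in self.stages}

    def surviving(self, stage: str) -> frozenset[str]:
        for label, genes in self.stages:
            if label == stage:
                return genes
        raise KeyError(stage)


def _median(values: Sequence[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def derive_thresholds(
    seeds: Iterable[str],
    constraint: ConstraintMap,
    expression: ExpressionMatrix,
) -> ThresholdSet:
    """Derive the cascade thresholds from the seed gene list.

    Seeds absent from a resource are excluded from that median, with the
    effective denominators recorded on the result. Raises ``ValueError``
    when no seed carries constraint (or expression) data.
    """
    seed_list = sorted(set(seeds))
    loeufs = [
        constraint[g].loeuf
        for g in seed_list
        if g in constraint and constraint[g].loeuf is not None
    ]
    expressed = [g for g in seed_list if g in expression]
    if not loeufs:
        raise ValueError("no seed gene has constraint data")
    if not expressed:
        raise ValueError("no seed gene has expression data")
    medians = expression.table.loc[expressed].median(axis=1)
    logger.info(
        "thresholds: %d/%d seeds with LOEUF, %d/%d with expression",
        len(loeufs), len(seed_list), len(expressed), len(seed_list),
    )
    return ThresholdSet(
        loeuf_max=_median(loeufs),
        tpm_min=_median(medians.tolist()),
        n_seeds_with_constraint=len(loeufs),
        n_seeds_with_expression=len(expressed),
    )


def _pathway_gene_pool(
    enriched: Sequence[EnrichmentResult],
    collections: Mapping[str, GeneSetCollection],
    pathway_mode: str,
    top_k: int,
) -> tuple[frozenset[str], tuple[str, ...]]:
    if pathway_mode == ALL_ENRICHED:
        selected = sorted(
            enriched, key=lambda r: (r.p_adjusted, r.p_raw, r.set_name)
        )
    elif pathway_mode == TOP_K:
        selected = select_top_sets(enriched, top_k)
    else:
        raise ValueError(f"unknown pathway_mode: {pathway_mode!r}")
    pool: set[str] = set()
    names: list[str] = []
    for result in selected:
        try:
            members = collections[result.collection].sets[result.set_name]
        except KeyError:
            raise KeyError(
                f"enriched set {result.set_name!r} not found in collection "
                f"{result.collection!r}"
            ) from None
        pool |= members
        names.append(result.set_name)
    return frozenset(pool), tuple(names)


def run_cascade(
    universe: Iterable[str],
    seeds: Iterable[str],
    thresholds: ThresholdSet,
    constraint: ConstraintMap,
    expression: ExpressionMatrix,
    network: InteractionNetwork,
    enriched: Sequence[EnrichmentResult],
    collections: Mapping[str, GeneSetCollection] | GeneSetCollection,
    disease_map: DiseaseMap | None = None,
    pathway_mode: str = ALL_ENRICHED,
    top_k: int = 10,
) -> CascadeResult:
    """Run the four-stage filter cascade over a gene universe.

    ``enriched`` is the significance-filtered enrichment output (the
    pathway stage trusts it); ``collections`` resolves set memberships.
    Genes missing constraint or expression values fail the corresponding
    stage (conservative; counts logged). The constraint filter is strict
    (LOEUF < loeuf_max), the expression filter inclusive
    (median TPM >= tpm_min). Seeds are removed only after the pathway
    stage; candidates are then split by disease-map membership.
    """
    if isinstance(collections, GeneSetCollection):
        collections = {collections.name: collections}
    universe_set = frozenset(universe)
    seed_set = frozenset(seeds)

    # stage 1: evolutionary constraint
    missing_constraint = 0
    stage1: set[str] = set()
    for gene in universe_set:
        entry = constraint.get(gene)
        if entry is None or entry.loeuf is None:
            missing_constraint += 1
            continue
        if entry.loeuf < thresholds.loeuf_max:
            stage1.add(gene)
    if missing_constraint:
        logger.info("cascade: %d gene(s) without LOEUF failed stage 1", missing_constraint)

    # stage 2: broad/high expression
    present = [g for g in stage1 if g in expression]
    missing_expression = len(stage1) - len(present)
    if missing_expression:
        logger.info("cascade: %d gene(s) without expression failed stage 2", missing_expression)
    if present:
        medians = expression.table.loc[present].median(axis=1)
        stage2 = set(medians[medians >= thresholds.tpm_min].index)
    else:
        stage2 = set()

    # stage 3: physical interaction with >=1 seed (other than itself)
    stage3 = {
        gene for gene in stage2 if network.neighbors(gene) & (seed_set - {gene})
    }

    # stage 4: membership in the enriched pathways
    pathway_pool, selected_names = _pathway_gene_pool(
        enriched, collections, pathway_mode, top_k
    )
    stage4 = stage3 & pathway_pool

    seed_overlap = frozenset(stage4 & seed_set)
    candidates = frozenset(stage4 - seed_set)
    known, novel = classify_candidates(candidates, disease_map or {})
    return CascadeResult(
        thresholds=thresholds,
        stages=(
            ("constraint", frozenset(stage1)),
            ("expression", frozenset(stage2)),
            ("ppi", frozenset(stage3)),
            ("pathway", frozenset(stage4)),
        ),
        pathway_mode=pathway_mode,
        selected_set_names=selected_names,
        seed_overlap=seed_overlap,
        candidates=candidates,
        known_disease=known,
        novel=novel,
    )


def classify_candidates(
    candidates: Iterable[str], disease_map: DiseaseMap
) -> tuple[frozenset[str], frozenset[str]]:
    """Split candidates into known disease genes and novel ones.

    Known = at least one disease association in the map; the two sets
    are disjoint and cover the candidates.
    """
    candidate_set = frozenset(candidates)
    known = frozenset(g for g in candidate_set if disease_map.get(g))
    return known, frozenset(candidate_set - known)


def run_full_pipeline(
    seeds: Iterable[str],
    constraint: ConstraintMap,
    expression: ExpressionMatrix,
    network: InteractionNetwork,
    collections: Mapping[str, GeneSetCollection] | GeneSetCollection,
    disease_map: DiseaseMap | None = None,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    pathway_mode: str = ALL_ENRICHED,
    top_k: int = 10,
) -> tuple[ThresholdSet, list[EnrichmentResult], CascadeResult]:
    """Threshold derivation, enrichment and cascade in one call.

    The universe defaults to every gene with constraint data (the
    whole-genome background); enrichment of the seed list runs per
    collection against that universe and the significance-filtered
    results feed the pathway stage.
    """
    from .enrichment import enrich, significant_results

    if isinstance(collections, GeneSetCollection):
        collections = {collections.name: collections}
    seed_set = frozenset(seeds)
    universe_set = frozenset(universe) if universe is not None else frozenset(constraint)
    thresholds = derive_thresholds(seed_set, constraint, expression)
    all_results: list[EnrichmentResult] = []
    for coll in collections.values():
        all_results.extend(enrich(seed_set, coll, universe=universe_set))
    enriched = significant_results(all_results, alpha=alpha)
    result = run_cascade(
        universe_set,
        seed_set,
        thresholds,
        constraint,
        expression,
        network,
        enriched,
        collections,
        disease_map=disease_map,
        pathway_mode=pathway_mode,
        top_k=top_k,
    )
    return thresholds, enriched, result


# ---------------------------------------------------------------------------
# Serialization of cascade output (used by the CLI)
# ---------------------------------------------------------------------------

def write_candidates(result: CascadeResult, path: str | Path) -> None:
    """One row per final-stage gene with stage provenance and the split."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tis_seed\tstatus\n")
        for gene in sorted(result.surviving("pathway")):
            if gene in result.seed_overlap:
                status = "seed"
            elif gene in result.known_disease:
                status = "known_disease"
            else:
                status = "novel"
            fh.write(f"{gene}\t{str(gene in result.seed_overlap).lower()}\t{status}\n")


def write_stages(result: CascadeResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stage\tn_genes\n")
        for label, genes in result.stages:
            fh.write(f"{label}\t{len(genes)}\n")
        fh.write(f"seed_overlap\t{len(result.seed_overlap)}\n")
        fh.write(f"candidates\t{len(result.candidates)}\n")
        fh.write(f"known_disease\t{len(result.known_disease)}\n")
        fh.write(f"novel\t{len(result.novel)}\n")


def write_thresholds(thresholds: ThresholdSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "loeuf_max": thresholds.loeuf_max,
                "tpm_min": thresholds.tpm_min,
                "n_seeds_with_constraint": thresholds.n_seeds_with_constraint,
                "n_seeds_with_expression": thresholds.n_seeds_with_expression,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
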