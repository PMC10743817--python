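"""Over-representation analysis of a gene list against gene-set collections.

The test is the one-sided hypergeometric upper tail (equivalently a
one-sided Fisher exact test): with a universe of ``N`` genes of which
``K`` belong to the set, and a query of ``n`` universe genes with ``k``
in the set, the reported p-value is ``P(X >= k)`` for hypergeometric
``X``. Multiple testing is corrected with the Benjamini-Hochberg step-up
procedure within each collection, mirroring the convention that GO BP,
GO CC, GO MF and MSigDB C2 are separate test families.

The module also houses the development-keyword classifier used to split
genes into development-annotated versus not: a term counts as
developmental when its name contains "development", "morphogenesis" or
"formation" (case-insensitive substring match; no ontology propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .resources import GeneSetCollection

logger = logging.getLogger(__name__)

DEVELOPMENT_KEYWORDS = ("development", "morphogenesis", "formation")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``N`` universe genes, ``K`` of them in the set, ``n`` drawn (the
    query), ``k`` of the drawn in the set. Computed through the survival
    function for numerical stability; ``k = 0`` gives exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent overlap k={k} for K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input-order aligned.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1. Written out explicitly rather than delegated, since the
    step-up correction is part of this package's core statistics.
    """
    m = len(p_values)
    if m == 0:
        return []
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p_values[idx] * m / rank)
        # clamp away sub-ulp rounding: the true step-up value never drops
        # below the raw p-value
        adjusted[idx] = max(running_min, p_values[idx])
    return adjusted


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap statistics and p-values for one gene set."""

    collection: str
    set_name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_size_N: int
    p_raw: float
    p_adjusted: float
    overlap_genes: frozenset[str] = frozenset()

    @property
    def is_development_term(self) -> bool:
        return is_development_term(self.set_name)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    min_overlap: int = 1,
    min_set_size: int = 5,
    max_set_size: int = 2000,
) -> list[EnrichmentResult]:
    """Test every set of a collection for over-representation in a query.

    The universe defaults to all genes annotated in >=1 set of the
    collection; query genes outside the universe are dropped (logged).
    Sets outside the configured size band are skipped; only sets with
    overlap >= ``min_overlap`` are reported. BH adjustment runs within
    the collection, and results come back sorted by adjusted then raw
    p-value, then set name.
    """
    universe_set = (
        collection.all_genes if universe is None else frozenset(universe)
    )
    query_set = frozenset(query)
    effective_query = query_set & universe_set
    dropped = len(query_set) - len(effective_query)
    if dropped:
        logger.info("enrich: dropped %d query gene(s) outside the universe", dropped)
    if not effective_query:
        raise ValueError("no query genes remain inside the universe")

    N = len(universe_set)
    n = len(effective_query)
    partial: list[tuple[str, int, int, frozenset[str]]] = []
    for set_name, members in collection.sets.items():
        members_in_universe = members & universe_set
        K = len(members_in_universe)
        if not min_set_size <= K <= max_set_size:
            continue
        overlap = effective_query & members_in_universe
        if len(overlap) < min_overlap:
            continue
        partial.append((set_name, len(overlap), K, overlap))

    p_raw = [hypergeometric_p(k, K, n, N) for _, k, K, _ in partial]
    p_adj = bh_adjust(p_raw)
    results = [
        EnrichmentResult(
            collection=collection.name,
            set_name=set_name,
            overlap_k=k,
            set_size_K=K,
            query_size_n=n,
            universe_size_N=N,
            p_raw=praw,
            p_adjusted=padj,
            overlap_genes=overlap,
        )
        for (set_name, k, K, overlap), praw, padj in zip(partial, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.set_name))
    return results


def significant_results(
    results: Iterable[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Sets passing the adjusted-significance threshold, sorted."""
    keep = [r for r in results if r.p_adjusted < alpha]
    keep.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.set_name))
    return keep


def select_top_sets(
    results: Sequence[EnrichmentResult], top_k: int
) -> list[EnrichmentResult]:
    """The ``top_k`` most significant sets, expanding ties at rank k.

    Ordering is (p_adjusted, p_raw, set_name); sets tied with the k-th on
    (p_adjusted, p_raw) are all included, and any expansion is logged.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ordered = sorted(results, key=lambda r: (r.p_adjusted, r.p_raw, r.set_name))
    if len(ordered) <= top_k:
        return ordered
    cutoff = (ordered[top_k - 1].p_adjusted, ordered[top_k - 1].p_raw)
    selected = [
        r for i, r in enumerate(ordered)
        if i < top_k or (r.p_adjusted, r.p_raw) == cutoff
    ]
    if len(selected) > top_k:
        logger.info(
            "select_top_sets: tie at rank %d expanded selection to %d sets",
            top_k,
            len(selected),
        )
    return selected


def is_development_term(term_name: str) -> bool:
    """True when the term name contains a development-related keyword."""
    lowered = term_name.lower()
    return any(keyword in lowered for keyword in DEVELOPMENT_KEYWORDS)


def development_split(
    genes: Iterable[str], go_annotation: GeneSetCollection
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition genes into development-annotated and unannotated.

    A gene is development-annotated iff it belongs to at least one term
    whose name matches :func:`is_development_term`. The two returned sets
    are disjoint and cover the input.
    """
    gene_set = frozenset(genes)
    dev_members: set[str] = set()
    for set_name, members in go_annotation.sets.items():
        if is_development_term(set_name):
            dev_members |= members
    annotated = frozenset(gene_set & dev_members)
    return annotated, frozenset(gene_set - annotated)
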