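"""Constraint and expression profiling of gene groups.

For a group of genes (an outcome stratum, the whole catalogue, or the
whole genome) this module reports how evolutionarily constrained the
group is (median LOEUF, proportions of pLI tolerance classes) and how it
is expressed (median expression breadth at a TPM cutoff, median of the
per-gene median TPM). Comparisons between groups are purely descriptive:
no inferential statistic is attached.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .resources import ConstraintMap, ExpressionMatrix


class ToleranceClass(str, enum.Enum):
    """pLI-based loss-of-function tolerance class of a gene."""

    TOLERANT = "tolerant"
    INTERMEDIATE = "intermediate"
    INTOLERANT = "intolerant"


def classify_pli(pli: float, strict_boundaries: bool = False) -> ToleranceClass:
    """Map a pLI value onto its tolerance class.

    By default boundaries are inclusive: tolerant iff pLI <= 0.1,
    intolerant iff pLI >= 0.9. ``strict_boundaries=True`` switches to
    strict inequalities (boundary values become intermediate); with
    continuous pLI the boundary mass is negligible either way.
    """
    if not 0.0 <= pli <= 1.0:
        raise ValueError(f"pLI {pli} outside [0, 1]")
    if strict_boundaries:
        if pli < 0.1:
            return ToleranceClass.TOLERANT
        if pli > 0.9:
            return ToleranceClass.INTOLERANT
    else:
        if pli <= 0.1:
            return ToleranceClass.TOLERANT
        if pli >= 0.9:
            return ToleranceClass.INTOLERANT
    return ToleranceClass.INTERMEDIATE


def expression_breadth(
    profile: "ExpressionProfileLike", tpm_threshold: float = 10.0
) -> int:
    """Count tissues where the gene is expressed at >= the TPM cutoff.

    The cutoff is inclusive ("at least"); the default of 10 TPM is the
    conventional broad-expression threshold.
    """
    if tpm_threshold <= 0:
        raise ValueError("tpm_threshold must be positive")
    values = profile.values
    if not values:
        raise ValueError(f"{profile.gene}: profile has no tissues")
    return int(sum(1 for v in values if v >= tpm_threshold))


class ExpressionProfileLike:
    """Protocol stub: anything with ``gene`` and ``values`` attributes."""

    gene: str
    values: Sequence[float]


@dataclass(frozen=True)
class GroupProfile:
    """Constraint and expression summary of one gene group.

    Medians use the even-length mean-of-central-pair convention.
    Constraint fields are computed over the genes with the respective
    metric present; expression fields over genes present in the matrix.
    Fields are None (absent, not zero) when no gene carries the data.
    """

    group_label: str
    n_genes: int
    n_genes_with_constraint: int
    median_loeuf: float | None
    tolerance_proportions: Mapping[ToleranceClass, float]
    n_genes_with_expression: int
    median_breadth: float | None
    median_of_median_tpm: float | None
    median_of_median_tpm_nonzero: float | None
    breadth_threshold: float


def profile_group(
    group_label: str,
    genes: Iterable[str],
    constraint: ConstraintMap | None = None,
    expression: ExpressionMatrix | None = None,
    breadth_threshold: float = 10.0,
    strict_boundaries: bool = False,
) -> GroupProfile:
    """Profile one gene group against the constraint and expression data.

    ``median_of_median_tpm_nonzero`` restricts the median to genes whose
    across-tissue median TPM is positive; both variants are reported
    because the all-genes background is dominated by unexpressed genes.
    """
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ValueError("cannot profile an empty gene group")

    median_loeuf = None
    proportions: dict[ToleranceClass, float] = {}
    n_constraint = 0
    if constraint is not None:
        loeufs = [
            constraint[g].loeuf
            for g in gene_list
            if g in constraint and constraint[g].loeuf is not None
        ]
        plis = [
            constraint[g].pli
            for g in gene_list
            if g in constraint and constraint[g].pli is not None
        ]
        n_constraint = sum(1 for g in gene_list if g in constraint)
        if loeufs:
            median_loeuf = float(np.median(loeufs))
        if plis:
            classes = [classify_pli(p, strict_boundaries) for p in plis]
            proportions = {
                cls: classes.count(cls) / len(classes) for cls in ToleranceClass
            }

    median_breadth = None
    median_of_median = None
    median_of_median_nonzero = None
    n_expression = 0
    if expression is not None:
        present = [g for g in gene_list if g in expression]
        n_expression = len(present)
        if present:
            sub = expression.table.loc[present]
            median_breadth = float((sub >= breadth_threshold).sum(axis=1).median())
            per_gene_median = sub.median(axis=1)
            median_of_median = float(per_gene_median.median())
            nonzero = per_gene_median[per_gene_median > 0]
            if len(nonzero):
                median_of_median_nonzero = float(nonzero.median())

    return GroupProfile(
        group_label=group_label,
        n_genes=len(gene_list),
        n_genes_with_constraint=n_constraint,
        median_loeuf=median_loeuf,
        tolerance_proportions=proportions,
        n_genes_with_expression=n_expression,
        median_breadth=median_breadth,
        median_of_median_tpm=median_of_median,
        median_of_median_tpm_nonzero=median_of_median_nonzero,
        breadth_threshold=breadth_threshold,
    )


def compare_groups(group_profiles: Sequence[GroupProfile]) -> pd.DataFrame:
    """Side-by-side table of group profiles plus differences of medians.

    Differences are taken against the first group; the comparison is
    descriptive only (no p-values).
    """
    if len(group_profiles) < 2:
        raise ValueError("compare_groups needs at least two groups")
    rows = []
    reference = group_profiles[0]
    for gp in group_profiles:
        row: dict[str, object] = {
            "group": gp.group_label,
            "n_genes": gp.n_genes,
            "n_genes_with_constraint": gp.n_genes_with_constraint,
            "median_loeuf": gp.median_loeuf,
            "n_genes_with_expression": gp.n_genes_with_expression,
            "median_breadth": gp.median_breadth,
            "median_of_median_tpm": gp.median_of_median_tpm,
            "median_of_median_tpm_nonzero": gp.median_of_median_tpm_nonzero,
        }
        for cls in ToleranceClass:
            row[f"prop_{cls.value}"] = gp.tolerance_proportions.get(cls)
        for metric in ("median_loeuf", "median_breadth", "median_of_median_tpm"):
            ours, theirs = getattr(gp, metric), getattr(reference, metric)
            row[f"delta_{metric}"] = (
                None if ours is None or theirs is None else ours - theirs
            )
        rows.append(row)
    return pd.DataFrame(rows)
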