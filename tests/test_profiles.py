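"""pLI tolerance classes, expression breadth and group profiling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plgenes.profiles import (
    ToleranceClass,
    classify_pli,
    compare_groups,
    expression_breadth,
    profile_group,
)
from plgenes.resources import ExpressionMatrix, GeneConstraint


def make_matrix(rows: dict[str, list[float]], tissues: list[str] | None = None):
    any_row = next(iter(rows.values()))
    tissues = tissues or [f"T{i}" for i in range(len(any_row))]
    return ExpressionMatrix(pd.DataFrame(rows, index=tissues).T)


class TestClassifyPli:
    @pytest.mark.parametrize(
        "pli, expected",
        [
            (0.95, ToleranceClass.INTOLERANT),
            (0.9, ToleranceClass.INTOLERANT),
            (0.0, ToleranceClass.TOLERANT),
            (0.1, ToleranceClass.TOLERANT),
            (0.5, ToleranceClass.INTERMEDIATE),
        ],
    )
    def test_inclusive_boundaries(self, pli, expected):
        assert classify_pli(pli) is expected

    def test_strict_mode_moves_boundaries_to_intermediate(self):
        assert classify_pli(0.9, strict_boundaries=True) is ToleranceClass.INTERMEDIATE
        assert classify_pli(0.1, strict_boundaries=True) is ToleranceClass.INTERMEDIATE
        assert classify_pli(0.95, strict_boundaries=True) is ToleranceClass.INTOLERANT

    @pytest.mark.parametrize("pli", [-0.01, 1.01])
    def test_out_of_domain_rejected(self, pli):
        with pytest.raises(ValueError):
            classify_pli(pli)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_total_partition(self, pli):
        assert classify_pli(pli) in ToleranceClass


class TestExpressionBreadth:
    def test_inclusive_threshold(self):
        matrix = make_matrix({"A": [12.0, 9.9, 10.0, 0.0]})
        assert expression_breadth(matrix.profile("A"), 10.0) == 2

    def test_all_zero_vector(self):
        matrix = make_matrix({"A": [0.0, 0.0, 0.0]})
        assert expression_breadth(matrix.profile("A"), 10.0) == 0

    def test_random_profile_matches_direct_recount(self):
        rng = np.random.default_rng(42)
        values = np.round(rng.lognormal(2.0, 1.0, size=40), 3).tolist()
        matrix = make_matrix({"A": values})
        recount = sum(1 for v in values if v >= 10.0)
        assert expression_breadth(matrix.profile("A"), 10.0) == recount

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(7)
        matrix = make_matrix({"A": rng.lognormal(1.5, 1.2, size=30).tolist()})
        profile = matrix.profile("A")
        breadths = [expression_breadth(profile, t) for t in (0.5, 1, 5, 10, 50)]
        assert breadths == sorted(breadths, reverse=True)

    def test_nonpositive_threshold_rejected(self):
        matrix = make_matrix({"A": [1.0]})
        with pytest.raises(ValueError):
            expression_breadth(matrix.profile("A"), 0.0)


def constraint_of(**loeuf_pli):
    return {
        gene: GeneConstraint(gene=gene, pli=pli, loeuf=loeuf)
        for gene, (loeuf, pli) in loeuf_pli.items()
    }


class TestProfileGroup:
    def test_odd_length_median_loeuf(self):
        cmap = constraint_of(A=(0.2, 0.5), B=(0.5, 0.5), C=(0.8, 0.5))
        gp = profile_group("g", ["A", "B", "C"], constraint=cmap)
        assert gp.median_loeuf == 0.5

    def test_tolerance_proportions_direct_fractions(self):
        cmap = constraint_of(
            A=(0.2, 0.05), B=(0.2, 0.05), C=(0.2, 0.5), D=(0.2, 0.95)
        )
        gp = profile_group("g", "ABCD", constraint=cmap)
        assert gp.tolerance_proportions[ToleranceClass.TOLERANT] == 0.5
        assert gp.tolerance_proportions[ToleranceClass.INTERMEDIATE] == 0.25
        assert gp.tolerance_proportions[ToleranceClass.INTOLERANT] == 0.25
        assert sum(gp.tolerance_proportions.values()) == pytest.approx(1.0)

    def test_even_length_median_is_mean_of_central_pair(self):
        matrix = make_matrix({"A": [4.0] * 4, "B": [20.0] * 4})
        gp = profile_group("g", ["A", "B"], expression=matrix)
        assert gp.median_of_median_tpm == 12.0

    def test_absent_resource_fields_are_none_not_zero(self):
        gp = profile_group("g", ["NOPE"], constraint={}, expression=None)
        assert gp.n_genes_with_constraint == 0
        assert gp.median_loeuf is None
        assert gp.median_breadth is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            profile_group("g", [])

    def test_union_counts_are_additive_over_disjoint_groups(self, small_world):
        genes = list(small_world.constraint)
        g1, g2 = genes[:40], genes[40:90]
        p1 = profile_group("a", g1, small_world.constraint, small_world.expression)
        p2 = profile_group("b", g2, small_world.constraint, small_world.expression)
        pu = profile_group("u", g1 + g2, small_world.constraint, small_world.expression)
        assert pu.n_genes == p1.n_genes + p2.n_genes
        assert (
            pu.n_genes_with_constraint
            == p1.n_genes_with_constraint + p2.n_genes_with_constraint
        )
        assert (
            pu.n_genes_with_expression
            == p1.n_genes_with_expression + p2.n_genes_with_expression
        )

    def test_min_tpm_selection_cannot_lower_the_median(self, small_world):
        expr = small_world.expression
        all_genes = expr.genes
        whole = profile_group("all", all_genes, expression=expr)
        medians = expr.median_tpm()
        selected = list(medians[medians >= whole.median_of_median_tpm].index)
        sub = profile_group("selected", selected, expression=expr)
        assert sub.median_of_median_tpm >= whole.median_of_median_tpm


class TestCompareGroups:
    def test_identical_groups_have_zero_differences(self):
        cmap = constraint_of(A=(0.2, 0.5), B=(0.6, 0.5))
        gp = profile_group("g", ["A", "B"], constraint=cmap)
        table = compare_groups([gp, gp])
        assert table["delta_median_loeuf"].tolist() == [0.0, 0.0]

    def test_planted_median_difference_sign_recovered(self):
        rng = np.random.default_rng(3)
        rpl_like = {
            f"R{i}": GeneConstraint(gene=f"R{i}", pli=0.5, loeuf=float(v))
            for i, v in enumerate(rng.normal(0.8, 0.1, 60))
        }
        non_rpl_like = {
            f"N{i}": GeneConstraint(gene=f"N{i}", pli=0.5, loeuf=float(abs(v)))
            for i, v in enumerate(rng.normal(0.4, 0.1, 60))
        }
        p_rpl = profile_group("rpl", rpl_like.keys(), constraint=rpl_like)
        p_non = profile_group("non_rpl", non_rpl_like.keys(), constraint=non_rpl_like)
        table = compare_groups([p_rpl, p_non]).set_index("group")
        assert table.loc["non_rpl", "delta_median_loeuf"] < 0

    def test_single_group_is_usage_error(self):
        cmap = constraint_of(A=(0.2, 0.5))
        gp = profile_group("g", ["A"], constraint=cmap)
        with pytest.raises(ValueError):
            compare_groups([gp])
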