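"""Hypergeometric ORA, BH adjustment and the development-keyword split."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from conftest import hypergeom_tail_bruteforce
from plgenes.enrichment import (
    bh_adjust,
    development_split,
    enrich,
    hypergeometric_p,
    is_development_term,
    select_top_sets,
    significant_results,
)
from plgenes.resources import GeneSetCollection


class TestHypergeometricP:
    def test_zero_overlap_gives_one(self):
        assert hypergeometric_p(0, 5, 5, 20) == 1.0

    def test_frozen_enumeration_value(self):
        # tail sum over j in {4, 5} of C(5,j) C(15,5-j) / C(20,5),
        # computed by hand from the enumeration oracle: 76/15504
        expected = 76 / 15504
        assert hypergeometric_p(4, 5, 5, 20) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_certainty(self):
        assert hypergeometric_p(7, 7, 7, 7) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_p(3, 2, 5, 20)
        with pytest.raises(ValueError):
            hypergeometric_p(1, 25, 5, 20)

    @given(
        st.integers(min_value=1, max_value=25).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=0, max_value=N),
                st.integers(min_value=0, max_value=N),
            )
        )
    )
    def test_matches_bruteforce_enumeration(self, NKn):
        N, K, n = NKn
        for k in range(max(0, K + n - N), min(K, n) + 1):
            assert hypergeometric_p(k, K, n, N) == pytest.approx(
                hypergeom_tail_bruteforce(k, K, n, N), rel=1e-9
            )


class TestBHAdjust:
    def test_hand_computed_step_up_oracle(self):
        # q_(i) = min_{j>=i} p_(j) * m / j applied by hand:
        # (0.005*4/1=0.02, 0.01*4/2=0.02, 0.03*4/3=0.04, 0.04*4/4=0.04)
        assert bh_adjust([0.005, 0.01, 0.03, 0.04]) == pytest.approx(
            [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == [0.37]

    def test_empty_input(self):
        assert bh_adjust([]) == []

    def test_adjusted_dominates_raw_and_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40)).tolist()
            adjusted = bh_adjust(p)
            assert all(a >= r for a, r in zip(adjusted, p))
            assert all(a <= 1.0 for a in adjusted)
            reference = multipletests(p, method="fdr_bh")[1]
            assert adjusted == pytest.approx(reference.tolist(), rel=1e-12)

    def test_permutation_equivariance(self):
        p = [0.04, 0.001, 0.7, 0.2, 0.02]
        adjusted = bh_adjust(p)
        perm = [3, 0, 4, 1, 2]
        permuted = bh_adjust([p[i] for i in perm])
        assert permuted == pytest.approx([adjusted[i] for i in perm])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def toy_collection():
    return GeneSetCollection(
        name="TOY",
        sets={
            "FIRST": frozenset({"A", "B", "C", "D", "E"}),
            "SECOND": frozenset({"F", "G", "H", "I", "J"}),
        },
    )


class TestEnrich:
    def test_query_identical_to_one_set_ranks_first(self):
        results = enrich({"A", "B", "C", "D", "E"}, toy_collection())
        assert results[0].set_name == "FIRST"
        assert results[0].overlap_k == 5
        assert results[0].p_raw < 0.01

    def test_zero_overlap_sets_are_not_reported(self):
        results = enrich({"F", "G"}, toy_collection())
        assert [r.set_name for r in results] == ["SECOND"]

    def test_query_outside_universe_dropped(self):
        results = enrich({"A", "B", "ZZZ"}, toy_collection())
        assert results[0].query_size_n == 2

    def test_empty_effective_query_is_usage_error(self):
        with pytest.raises(ValueError):
            enrich({"ZZZ"}, toy_collection())

    def test_invariant_to_query_ordering(self):
        a = enrich(["A", "C", "B"], toy_collection())
        b = enrich(["B", "A", "C"], toy_collection())
        assert a == b

    def test_set_size_band_filters(self):
        coll = GeneSetCollection(
            name="X",
            sets={"TINY": frozenset({"A", "B"}), "OK": frozenset("ABCDE")},
        )
        results = enrich({"A"}, coll, min_set_size=5)
        assert [r.set_name for r in results] == ["OK"]

    def test_shrinking_universe_never_increases_N(self):
        full = enrich({"A", "B"}, toy_collection())
        shrunk = enrich({"A", "B"}, toy_collection(), universe=set("ABCDEFG"))
        assert shrunk[0].universe_size_N <= full[0].universe_size_N

    def test_result_invariants(self, small_world):
        seeds = set(small_world.ground_truth.seeds)
        for r in enrich(seeds, small_world.collection, universe=set(small_world.genes)):
            assert 0 <= r.overlap_k <= min(r.set_size_K, r.query_size_n)
            assert r.set_size_K <= r.universe_size_N
            assert 0 < r.p_raw <= 1
            assert r.p_adjusted >= r.p_raw


class TestTopKSelection:
    def test_top_k_subset_of_all_significant(self, small_world):
        seeds = set(small_world.ground_truth.seeds)
        results = significant_results(
            enrich(seeds, small_world.collection, universe=set(small_world.genes))
        )
        top = select_top_sets(results, 1)
        assert {r.set_name for r in top} <= {r.set_name for r in results}

    def test_ties_at_rank_k_are_expanded(self):
        results = enrich({"A", "F"}, toy_collection())
        # both sets have identical (k, K, n, N), hence identical p-values
        assert len(select_top_sets(results, 1)) == 2

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            select_top_sets([], 0)


class TestDevelopmentTerms:
    @pytest.mark.parametrize(
        "term, expected",
        [
            ("epithelial tube morphogenesis", True),
            ("heart development", True),
            ("Formation of primary germ layer", True),
            ("calcium ion binding", False),
        ],
    )
    def test_keyword_match(self, term, expected):
        assert is_development_term(term) is expected

    def test_split_is_a_partition(self):
        coll = GeneSetCollection(
            name="GO",
            sets={
                "heart development": frozenset({"A"}),
                "ion transport": frozenset({"B", "C"}),
            },
        )
        annotated, unannotated = development_split({"A", "B", "C", "D"}, coll)
        assert annotated == {"A"}
        assert unannotated == {"B", "C", "D"}
        assert not annotated & unannotated

    def test_planted_proportions_recovered_exactly(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i:03d}" for i in range(200)]
        planted_dev = set(g for g in genes if rng.random() < 0.55)
        coll = GeneSetCollection(
            name="GO",
            sets={
                "embryo development": frozenset(planted_dev),
                "metabolic process": frozenset(genes[:50]),
            },
        )
        annotated, unannotated = development_split(genes, coll)
        assert annotated == planted_dev
        assert len(annotated) + len(unannotated) == len(genes)
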