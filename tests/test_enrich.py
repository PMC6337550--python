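"""Hypergeometric test, p adjustment, Cohen's kappa, term grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbnet.enrich import (
    GeneSetCollection,
    adjust_p,
    enrich,
    enrich_and_group,
    group_terms,
    hypergeom_p,
    kappa,
)
from herbnet.errors import HerbnetError, ValidationError
from oracles import hypergeom_tail_exact


class TestHypergeomP:
    def test_all_marked_draw(self):
        # drawing all 5 marked out of 5 in 5 draws from 20: 1/C(20,5)
        assert hypergeom_p(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_p(0, 7, 3, 30) == 1.0

    def test_term_equals_universe_is_certain(self):
        assert hypergeom_p(1, 12, 1, 12) == 1.0

    def test_matches_exact_arithmetic_on_a_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            assert hypergeom_p(k, K, n, N) == pytest.approx(
                hypergeom_tail_exact(k, K, n, N), rel=1e-9)

    @pytest.mark.parametrize("args", [(-1, 5, 5, 20), (6, 5, 5, 20), (2, 25, 5, 20), (2, 5, 25, 20)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValidationError):
            hypergeom_p(*args)


class TestAdjustP:
    def test_single_p_unchanged(self):
        assert adjust_p([0.03], "bonferroni_step_down")[0] == pytest.approx(0.03)

    def test_holm_worked_example(self):
        np.testing.assert_allclose(
            adjust_p([0.01, 0.02, 0.03], "bonferroni_step_down"), [0.03, 0.04, 0.04])

    def test_equal_ps_stay_equal(self):
        for method in ("benjamini_hochberg", "bonferroni_step_down"):
            adj = adjust_p([0.02] * 5, method)
            assert len(set(np.round(adj, 12))) == 1

    def test_bh_preserves_order(self):
        p = [0.001, 0.5, 0.04, 0.9, 0.01]
        adj = adjust_p(p, "benjamini_hochberg")
        assert list(np.argsort(adj)) == list(np.argsort(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_p([0.5, 1.2])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            adjust_p([0.5], "bonferroni")


class TestKappa:
    U8 = set("12345678")

    def test_identical_sets(self):
        assert kappa({"1", "2"}, {"1", "2"}, self.U8) == 1.0

    def test_half_overlap_is_chance_level(self):
        assert kappa(set("1234"), set("3456"), self.U8) == pytest.approx(0.0)

    def test_complementary_halves(self):
        assert kappa(set("1234"), set("5678"), self.U8) == pytest.approx(-1.0)

    def test_degenerate_chance_agreement(self):
        assert kappa(set(), set(), self.U8) == 1.0
        assert kappa(self.U8, self.U8, self.U8) == 1.0

    def test_empty_universe_is_an_error(self):
        with pytest.raises(HerbnetError):
            kappa({"a"}, {"a"}, set())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    def test_symmetric_and_bounded(self, a, b):
        u = set(range(16))
        k1, k2 = kappa(a, b, u), kappa(b, a, u)
        assert k1 == pytest.approx(k2)
        assert -1.0 - 1e-12 <= k1 <= 1.0 + 1e-12


def collection(terms, universe=None):
    return GeneSetCollection(
        terms={t: (f"desc {t}", frozenset(m)) for t, m in terms.items()},
        universe=frozenset(universe) if universe else frozenset(),
    )


class TestEnrichAndGroup:
    def test_overrepresented_term_ranks_first_and_significant(self):
        universe = {f"G{i}" for i in range(100)}
        hit = {f"G{i}" for i in range(10)}
        coll = collection(
            {"HIT": hit, "MISS1": {f"G{i}" for i in range(50, 60)},
             "MISS2": {f"G{i}" for i in range(60, 80)}},
            universe,
        )
        results, groups = enrich_and_group({f"G{i}" for i in range(10)}, coll)
        assert results[0].term_id == "HIT" and results[0].significant
        assert results[0].k == 10

    def test_disjoint_significant_terms_form_singleton_groups(self):
        universe = {f"G{i}" for i in range(60)}
        coll = collection(
            {"A": {f"G{i}" for i in range(5)}, "B": {f"G{i}" for i in range(30, 35)}},
            universe,
        )
        results, groups = enrich_and_group({f"G{i}" for i in range(5)} | {f"G{i}" for i in range(30, 35)}, coll)
        assert len(groups) == 2
        assert all(len(g.member_term_ids) == 1 for g in groups)

    def test_duplicated_term_joins_one_group(self):
        universe = {f"G{i}" for i in range(60)}
        members = {f"G{i}" for i in range(5)}
        coll = collection({"A": members, "A2": set(members)}, universe)
        results, groups = enrich_and_group(members, coll)
        assert len(groups) == 1
        assert sorted(groups[0].member_term_ids) == ["A", "A2"]
        assert groups[0].kappa_matrix[("A", "A2")] == 1.0

    def test_representative_is_lowest_p_member(self):
        universe = {f"G{i}" for i in range(80)}
        strong = {f"G{i}" for i in range(8)}
        weak = strong | {f"G{i}" for i in range(40, 50)}  # overlaps candidates less tightly
        coll = collection({"STRONG": strong, "WEAK": weak}, universe)
        results, groups = enrich_and_group(strong, coll, kappa_threshold=0.3)
        by_id = {r.term_id: r for r in results}
        if len(groups) == 1:
            assert by_id[groups[0].representative].p == min(r.p for r in results if r.significant)

    def test_raising_alpha_never_removes_significance(self):
        universe = {f"G{i}" for i in range(100)}
        coll = collection({f"T{j}": {f"G{i}" for i in range(j, j + 10)} for j in range(0, 50, 10)}, universe)
        cand = {f"G{i}" for i in range(12)}
        low = {r.term_id for r in enrich(cand, coll, alpha=0.01) if r.significant}
        high = {r.term_id for r in enrich(cand, coll, alpha=0.2) if r.significant}
        assert low <= high

    def test_raising_kappa_threshold_never_merges_groups(self):
        universe = {f"G{i}" for i in range(60)}
        coll = collection(
            {"A": {f"G{i}" for i in range(6)}, "B": {f"G{i}" for i in range(3, 9)},
             "C": {f"G{i}" for i in range(5, 11)}},
            universe,
        )
        cand = {f"G{i}" for i in range(11)}
        results = enrich(cand, coll)
        loose = group_terms(results, coll, kappa_threshold=0.2)
        tight = group_terms(results, coll, kappa_threshold=0.8)
        assert len(tight) >= len(loose)

    def test_no_candidates_in_universe_is_an_error(self):
        coll = collection({"A": {"G1"}}, {"G1", "G2"})
        with pytest.raises(HerbnetError):
            enrich({"ZZZ"}, coll)

    def test_no_significant_terms_gives_empty_groups(self):
        universe = {f"G{i}" for i in range(20)}
        coll = collection({"A": {f"G{i}" for i in range(10)}}, universe)
        results, groups = enrich_and_group({"G0", "G15"}, coll)
        assert all(not r.significant for r in results)
        assert groups == []

    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            collection({"A": {"G1", "X"}}, {"G1"})
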