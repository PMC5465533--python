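import math
from itertools import combinations
from math import comb

import numpy as np
import pytest

from lnctissue.errors import UsageError
from lnctissue.interactions import LocalInteractionSite, score_pairs
from lnctissue.prediction import (
    CandidateSet,
    bonferroni,
    fisher_enrichment,
    hypergeom_tail_p,
    random_baseline,
    rank_candidates,
    select_candidates,
    tp_curve,
)
from lnctissue.specificity import TissueGeneSets


def scores_from(energies_by_mrna, cutoff=-16.0):
    sites = [
        LocalInteractionSite("L1", mrna, 1, 10, 1, 10, e)
        for mrna, elist in energies_by_mrna.items()
        for e in elist
    ]
    return score_pairs(sites, cutoff)


class TestSelectCandidates:
    initial = CandidateSet("initial", ("m1", "m2", "m3"))

    def test_intersection_keeps_initial_order(self):
        sets = TissueGeneSets({"skin": frozenset({"m3", "m2", "m9"})})
        cand = select_candidates(self.initial, sets, "skin")
        assert cand.mrna_ids == ("m2", "m3")
        assert cand.label == "tissue:skin"

    def test_disjoint_sets_allowed(self):
        sets = TissueGeneSets({"skin": frozenset({"m9"})})
        assert select_candidates(self.initial, sets, "skin").mrna_ids == ()

    def test_superset_gives_back_initial(self):
        sets = TissueGeneSets({"skin": frozenset({"m1", "m2", "m3", "m4"})})
        cand = select_candidates(self.initial, sets, "skin")
        assert cand.mrna_ids == self.initial.mrna_ids

    def test_unknown_tissue_lists_available(self):
        sets = TissueGeneSets({"skin": frozenset()})
        with pytest.raises(UsageError, match="skin"):
            select_candidates(self.initial, sets, "esophagus")


class TestRankCandidates:
    def test_most_negative_sum_first(self):
        scores = scores_from({"m1": [-20, -20], "m2": [-19, -19], "m3": [-10]})
        cand = CandidateSet("initial", ("m1", "m2", "m3"))
        assert rank_candidates(scores, cand, "SumEnergy") == ["m1", "m2", "m3"]

    def test_ties_break_lexicographically(self):
        scores = scores_from({"mB": [-20], "mA": [-20]})
        cand = CandidateSet("initial", ("mB", "mA"))
        assert rank_candidates(scores, cand, "SumEnergy") == ["mA", "mB"]

    def test_min_and_sum_orderings_can_disagree(self):
        # m1 has two moderate sites, m2 one strong site
        scores = scores_from({"m1": [-17, -17], "m2": [-20]})
        cand = CandidateSet("initial", ("m1", "m2"))
        assert rank_candidates(scores, cand, "MinEnergy") == ["m2", "m1"]
        assert rank_candidates(scores, cand, "SumEnergy") == ["m1", "m2"]

    def test_unscored_candidates_rank_last(self):
        scores = scores_from({"m2": [-20]})
        cand = CandidateSet("initial", ("m9", "m2", "m5"))
        for method in ("MinEnergy", "SumEnergy"):
            assert rank_candidates(scores, cand, method) == ["m2", "m5", "m9"]

    def test_no_qualifying_sites_sort_after_qualifying(self):
        scores = scores_from({"m1": [-15.0], "m2": [-16.5]})
        cand = CandidateSet("initial", ("m1", "m2"))
        assert rank_candidates(scores, cand, "SumEnergy") == ["m2", "m1"]

    def test_empty_candidates_and_bad_method(self):
        assert rank_candidates([], CandidateSet("initial", ()), "SumEnergy") == []
        with pytest.raises(UsageError):
            rank_candidates([], CandidateSet("initial", ()), "MaxEnergy")


class TestTpCurve:
    def test_cumulative_hits(self):
        c = tp_curve(["t1", "f1", "t2"], {"t1", "t2"})
        np.testing.assert_array_equal(c.tp_counts, [1, 1, 2])

    def test_disjoint_truth_gives_zeros(self, caplog):
        c = tp_curve(["a", "b"], {"x"})
        np.testing.assert_array_equal(c.tp_counts, [0, 0])
        assert c.n_truth == 0  # off-universe truth dropped with a warning
        assert "dropping" in caplog.text

    def test_truth_superset_counts_every_depth(self):
        c = tp_curve(["a", "b", "c"], {"a", "b", "c", "z"})
        np.testing.assert_array_equal(c.tp_counts, [1, 2, 3])

    def test_depth_truncated_by_n_max(self):
        c = tp_curve(list("abcdef"), {"a"}, n_max=3)
        assert len(c.depths) == 3

    def test_reaches_full_truth_at_full_depth(self):
        rng = np.random.default_rng(2)
        ranking = [f"m{i}" for i in rng.permutation(50)]
        truth = set(ranking[::7])
        c = tp_curve(ranking, truth, n_max=50)
        assert c.tp_counts[-1] == len(truth)
        assert (np.diff(c.tp_counts) >= 0).all()
        assert (c.tp_counts <= c.depths).all()

    def test_empty_ranking(self):
        c = tp_curve([], {"a"})
        assert len(c.depths) == 0

    def test_baseline_is_hypergeometric_mean(self):
        c = tp_curve(list("abcdefghij"), {"a", "b", "c"}, n_max=10)
        np.testing.assert_allclose(c.baseline, np.arange(1, 11) * 0.3)


class TestRandomBaseline:
    def test_closed_form(self):
        assert random_baseline(100, 50, 5000) == pytest.approx(1.0)
        assert random_baseline(7, 30, 30) == 7

    def test_equals_exhaustive_enumeration(self):
        # brute-force mean over all C(30,10) draws, via the pmf identity
        n, K, M = 10, 3, 30
        mean = sum(
            k * comb(K, k) * comb(M - K, n - k) / comb(M, n)
            for k in range(0, K + 1)
        )
        assert random_baseline(n, K, M) == pytest.approx(mean)
        assert mean == pytest.approx(1.0)

    def test_invalid_arguments(self):
        with pytest.raises(UsageError):
            random_baseline(31, 3, 30)
        with pytest.raises(UsageError):
            random_baseline(1, 31, 30)


def exact_tail(a, b, c, d):
    """Hypergeometric tail by exact integer summation."""
    s, t, K = a + b, c + d, a + c
    numer = sum(
        comb(s, i) * comb(t, K - i) for i in range(a, min(s, K) + 1)
    )
    return numer / comb(s + t, K)


class TestFisherEnrichment:
    def test_extreme_concentration_closed_form(self):
        # subset of size K holding all K truth genes among M candidates
        M, K = 12, 4
        initial = CandidateSet("initial", tuple(f"m{i}" for i in range(M)))
        subset = CandidateSet("tissue:x", initial.mrna_ids[:K])
        truth = set(initial.mrna_ids[:K])
        res = fisher_enrichment(initial, subset, truth)
        assert res.p_value == pytest.approx(1 / comb(M, K), rel=1e-12)
        assert math.isinf(res.odds_ratio)

    def test_proportional_truth_is_not_enriched(self):
        initial = CandidateSet("initial", tuple(f"m{i}" for i in range(20)))
        subset = CandidateSet("tissue:x", initial.mrna_ids[:10])
        truth = {"m0", "m1", "m10", "m11"}  # same fraction inside and out
        assert fisher_enrichment(initial, subset, truth).p_value >= 0.5

    def test_table_tail_matches_direct_summation(self):
        assert hypergeom_tail_p(8, 2, 12, 78) == pytest.approx(
            exact_tail(8, 2, 12, 78), abs=1e-12
        )

    def test_table_counts(self):
        initial = CandidateSet("initial", tuple(f"m{i}" for i in range(10)))
        subset = CandidateSet("tissue:x", initial.mrna_ids[:4])
        res = fisher_enrichment(initial, subset, {"m0", "m1", "m5"})
        assert res.table == ((2, 2), (1, 5))
        assert res.odds_ratio == pytest.approx((2 * 5) / (2 * 1))

    def test_subset_must_be_contained(self):
        initial = CandidateSet("initial", ("m1", "m2"))
        subset = CandidateSet("tissue:x", ("m3",))
        with pytest.raises(UsageError):
            fisher_enrichment(initial, subset, set())


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni([0.01]), [0.01])
        np.testing.assert_allclose(bonferroni([0.01, 0.2]), [0.02, 0.4])
        np.testing.assert_allclose(bonferroni([0.9, 0.9]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            bonferroni([0.5, 1.2])


class TestRestrictionProperty:
    def test_subset_holding_all_truth_never_loses_tps(self):
        """Restricting candidates to a truth-covering subset cannot lower the
        TP count at any depth within the subset's size."""
        rng = np.random.default_rng(8)
        energies = {f"m{i:02d}": [float(rng.uniform(-30, -5))] for i in range(40)}
        scores = scores_from(energies)
        initial = CandidateSet("initial", tuple(sorted(energies)))
        truth = set(rng.choice(sorted(energies), 8, replace=False))
        subset_ids = tuple(
            m for m in initial.mrna_ids
            if m in truth or rng.random() < 0.3
        )
        subset = CandidateSet("tissue:x", subset_ids)
        full = tp_curve(rank_candidates(scores, initial), truth, n_max=40)
        sub = tp_curve(rank_candidates(scores, subset), truth, n_max=40)
        for i, n in enumerate(sub.depths):
            assert sub.tp_counts[i] >= full.tp_counts[n - 1]
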