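import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import minipsc as mp
from minipsc.evaluate import ConfusionCounts


class TestMatchEvents:
    def test_identical_lists_fully_matched(self):
        times = [0.1, 0.5, 0.9]
        m = mp.match_events(times, times, tol=1e-3)
        assert len(m.pairs) == 3
        assert m.unmatched_detected == [] and m.unmatched_reference == []

    def test_tolerance_boundary(self):
        ref = np.array([0.1, 0.5, 0.9])
        m = mp.match_events(ref + 0.5 * 1.2e-3, ref, tol=1.2e-3)
        assert len(m.pairs) == 3
        m = mp.match_events(ref + 2 * 1.2e-3, ref, tol=1.2e-3)
        assert len(m.pairs) == 0

    def test_two_detections_one_reference_single_pair(self):
        tol = 1.2e-3
        ref = [0.5]
        det = [0.5 - 0.2 * tol, 0.5 + 0.2 * tol]
        m = mp.match_events(det, ref, tol)
        assert len(m.pairs) == 1
        assert len(m.unmatched_detected) == 1

    def test_greedy_matches_optimal_when_events_are_separated(self, rng):
        # brute-force maximum matching (assignment enumeration) agrees with
        # the greedy matcher whenever neighbouring events are separated by
        # more than 2*tol, the regime of real recordings (events hundreds of
        # ms apart, tol 1.2 ms); greedy never over-matches in any regime
        tol = 1.2e-3

        def brute_force(det, ref):
            best = 0
            for k in range(min(len(det), len(ref)), 0, -1):
                for det_sub in itertools.combinations(range(len(det)), k):
                    for perm in itertools.permutations(range(len(ref)), k):
                        if all(abs(det[i] - ref[j]) <= tol
                               for i, j in zip(det_sub, perm)):
                            return k
            return best

        for trial in range(30):
            ref = np.cumsum(rng.uniform(3 * tol, 10 * tol, rng.integers(1, 6)))
            jitter = rng.uniform(-1.5 * tol, 1.5 * tol, ref.size)
            det = np.sort(ref + jitter)
            m = mp.match_events(det, ref, tol=tol)
            assert len(m.pairs) == brute_force(det, ref)

        # and on arbitrary crowded instances greedy is a valid (sub)matching
        det = np.sort(rng.uniform(0, 0.01, 6))
        ref = np.sort(rng.uniform(0, 0.01, 5))
        m = mp.match_events(det, ref, tol=tol)
        assert len(m.pairs) <= brute_force(det, ref)
        assert all(abs(d - r) <= tol for d, r in m.pairs)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            mp.match_events([0.1], [0.1], tol=-1.0)


class TestConfusion:
    def test_perfect_detection(self):
        ref = [0.1, 0.2, 0.3]
        c = mp.confusion(ref, ref, ref, tol=1e-3)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 0, 0, 0)

    def test_no_candidates(self):
        c = mp.confusion([], [], [0.1, 0.2], tol=1e-3)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 2)

    def test_mixed_instance_matches_hand_enumeration(self):
        # 5 candidates, 3 references; candidate 0.100 and 0.200 match refs,
        # ref 0.300 is missed, two spurious candidates: one accepted (FP),
        # one rejected (TN); the rejected candidate at 0.2001 shadows a
        # matched reference and counts toward nothing
        cands = [0.100, 0.150, 0.200, 0.2001, 0.400]
        accepted = [0.100, 0.150, 0.200]
        ref = [0.100, 0.200, 0.300]
        c = mp.confusion(cands, accepted, ref, tol=1e-3)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)

    def test_count_conservation(self):
        cands = [0.1, 0.2, 0.3, 0.4]
        accepted = [0.1, 0.3]
        ref = [0.1, 0.25]
        c = mp.confusion(cands, accepted, ref, tol=1e-3)
        assert c.tp + c.fp == len(accepted)
        assert c.tp + c.fn == len(ref)

    def test_accepted_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            mp.confusion([0.1], [0.2], [0.1], tol=1e-3)


class TestRocMetrics:
    def test_printed_formula_arithmetic(self):
        m = mp.roc_metrics(ConfusionCounts(tp=8, fp=2, tn=6, fn=4))
        assert m.fpr == pytest.approx(0.25)
        assert m.tpr == pytest.approx(8 / 12)
        assert m.accuracy == pytest.approx(0.70)
        assert m.fdr == pytest.approx(0.20)

    def test_zero_false_positives(self):
        m = mp.roc_metrics(ConfusionCounts(tp=5, fp=0, tn=3, fn=0))
        assert m.fpr == 0.0 and m.fdr == 0.0 and m.accuracy == 1.0

    def test_undefined_metrics_are_none(self):
        m = mp.roc_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))
        assert m.fpr is None and m.tpr is None and m.accuracy is None and m.fdr is None


class TestMcc:
    def test_perfect_agreement(self):
        assert mp.mcc(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0

    def test_chance_agreement(self):
        assert mp.mcc(ConfusionCounts(tp=5, fp=5, tn=5, fn=5)) == 0.0

    def test_arithmetic(self):
        c = ConfusionCounts(tp=6, fp=1, tn=3, fn=2)
        assert mp.mcc(c) == pytest.approx(16 / np.sqrt(1120), abs=1e-4)

    def test_zero_marginal_convention(self):
        assert mp.mcc(ConfusionCounts(tp=3, fp=0, tn=0, fn=0)) == 0.0

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    def test_bounded(self, tp, fp, tn, fn):
        assert -1.0 <= mp.mcc(ConfusionCounts(tp, fp, tn, fn)) <= 1.0


class TestRaterGrid:
    def test_rater_vs_itself_is_one(self):
        pool = [0.1, 0.2, 0.3, 0.4]
        acc = [0.1, 0.3]
        grid = mp.rater_mcc_grid([acc, acc], [pool, pool], tol=1e-3)
        np.testing.assert_allclose(grid, np.ones((2, 2)))

    def test_disjoint_selections_give_nonpositive_mcc(self):
        pool = [0.1, 0.2, 0.3, 0.4]
        grid = mp.rater_mcc_grid([[0.1, 0.2], [0.3, 0.4]], [pool, pool], tol=1e-3)
        assert grid[0, 1] <= 0.0

    def test_grid_symmetric_with_unit_diagonal(self, rng):
        pools, accs = [], []
        for _ in range(4):
            pool = np.sort(rng.uniform(0, 30, 40))
            accs.append(pool[rng.random(40) < 0.6])
            pools.append(pool)
        grid = mp.rater_mcc_grid(accs, pools, tol=1.2e-3)
        np.testing.assert_allclose(grid, grid.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(grid), 1.0)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            mp.rater_mcc_grid([[0.1]], [[0.1]])


class TestPairedPermutation:
    def test_n15_enumerates_32768_assignments(self, rng):
        a = rng.normal(0, 1, 15)
        b = a + rng.normal(0.5, 0.5, 15)
        res = mp.paired_permutation_test(a, b, mode="exhaustive")
        assert res.n_permutations == 32_768

    def test_identical_scores_give_p_one(self):
        a = np.array([0.4, 0.5, 0.6])
        res = mp.paired_permutation_test(a, a, mode="exhaustive")
        assert res.observed_diff == 0.0 and res.p_value == 1.0

    def test_minimum_p_for_clear_effect(self, rng):
        a = rng.normal(0, 0.01, 12)
        b = a + 1.0
        res = mp.paired_permutation_test(a, b, mode="exhaustive")
        # all-same-sign differences: only the two all-flip assignments tie
        assert res.p_value == pytest.approx(2 / 2 ** 12)

    def test_sign_symmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.3, 0.2, 10)
        r1 = mp.paired_permutation_test(a, b, mode="exhaustive")
        r2 = mp.paired_permutation_test(b, a, mode="exhaustive")
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff)

    def test_monte_carlo_within_3se_of_exhaustive(self, rng):
        a = rng.normal(0, 1, 8)
        b = a + rng.normal(0.4, 0.6, 8)
        exact = mp.paired_permutation_test(a, b, mode="exhaustive")
        mc = mp.paired_permutation_test(a, b, mode="monte_carlo",
                                        n_mc=100_000, seed=1)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 100_000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / 100_000

    def test_exhaustive_beyond_25_subjects_rejected(self, rng):
        a = rng.normal(0, 1, 26)
        with pytest.raises(ValueError, match="25"):
            mp.paired_permutation_test(a, a + 1, mode="exhaustive")
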