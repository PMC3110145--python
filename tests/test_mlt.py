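"""Optimal multilevel thresholding: moments, scores, DP vs exhaustive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omtgrid.mlt import (
    IntensityHistogram,
    ThresholdSet,
    between_class_score,
    brute_force_thresholds,
    class_moments,
    optimal_thresholds,
    optimal_thresholds_upto,
)


def hist(vals):
    return IntensityHistogram(np.asarray(vals, dtype=float))


class TestHistogram:
    def test_probabilities_normalized(self):
        h = hist([1, 2, 3, 4])
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [[1.0], [-1, 2], [0, 0], [np.nan, 1]])
    def test_invalid_histograms_rejected(self, bad):
        with pytest.raises(ValueError):
            hist(bad)


class TestClassMoments:
    def test_full_range_has_unit_weight(self):
        h = hist([3, 1, 4, 1, 5])
        w, _ = class_moments(h, 1, h.n)
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_single_bin_mean_is_its_position(self):
        h = hist([0.1, 0.7, 0.2])
        _, mu = class_moments(h, 2, 2)
        assert mu == 2.0

    def test_hand_computed_subrange(self):
        # h = [.2,.3,.5], bins 2..3: w=.8, mu=(2*.3+3*.5)/.8 = 2.625
        h = hist([0.2, 0.3, 0.5])
        w, mu = class_moments(h, 2, 3)
        assert w == pytest.approx(0.8, abs=1e-12)
        assert mu == pytest.approx(2.625, abs=1e-12)

    def test_moments_match_direct_summation(self):
        rng = np.random.default_rng(5)
        h = hist(rng.random(17))
        p = h.probabilities
        for a, b in [(1, 17), (3, 9), (5, 5), (2, 16)]:
            w, mu = class_moments(h, a, b)
            wref = p[a - 1 : b].sum()
            assert w == pytest.approx(wref, rel=1e-12)
            muref = (np.arange(a, b + 1) * p[a - 1 : b]).sum() / wref
            assert mu == pytest.approx(muref, rel=1e-10)

    def test_reversed_range_is_an_error(self):
        with pytest.raises(ValueError):
            class_moments(hist([1, 1, 1]), 3, 2)


class TestBetweenClassScore:
    def test_single_class_is_weighted_square_mean(self):
        h = hist([0.2, 0.3, 0.5])
        T = ThresholdSet(thresholds=(), score=0.0, n=3)
        w, mu = class_moments(h, 1, 3)
        assert between_class_score(h, T) == pytest.approx(w * mu * mu, rel=1e-12)

    def test_symmetric_bimodal_hand_value(self):
        # classes {1} and {2,3}: .5*1^2 + .5*3^2 = 5.0
        h = hist([0.5, 0.0, 0.5])
        T = ThresholdSet(thresholds=(1,), score=0.0, n=3)
        assert between_class_score(h, T) == pytest.approx(5.0, abs=1e-12)

    def test_centered_form_differs_by_global_mean_square(self):
        # sum w_j mu_j^2 == sum w_j (mu_j - mu)^2 + mu^2, to 1e-12
        rng = np.random.default_rng(11)
        h = hist(rng.random(20))
        p = h.probabilities
        mu = (np.arange(1, 21) * p).sum()
        T = optimal_thresholds(h, 3)
        centered = 0.0
        for a, b in T.classes():
            w, m = class_moments(h, a, b)
            centered += w * (m - mu) ** 2
        assert between_class_score(h, T) == pytest.approx(centered + mu * mu, abs=1e-12)

    def test_zero_mass_class_contributes_nothing(self):
        h = hist([0.5, 0.0, 0.0, 0.5])
        split_gap = ThresholdSet(thresholds=(2,), score=0.0, n=4)
        merged = ThresholdSet(thresholds=(1,), score=0.0, n=4)
        # both isolate the same masses; the empty stripe placement is free
        assert between_class_score(h, split_gap) == pytest.approx(
            between_class_score(h, merged), abs=1e-12
        )


class TestOptimalThresholds:
    def test_symmetric_tie_resolves_to_smaller_threshold(self):
        T = optimal_thresholds(hist([0.5, 0.0, 0.5]), 1)
        assert T.thresholds == (1,)

    def test_uniform_even_histogram_splits_in_the_middle(self):
        T = optimal_thresholds(hist([1, 1, 1, 1]), 1)
        assert T.thresholds == (2,)

    def test_threshold_lands_in_zero_gap_between_blocks(self):
        h = hist([4, 4, 4, 0, 0, 0, 4, 4, 4])
        T = optimal_thresholds(h, 1)
        assert 3 <= T.thresholds[0] <= 6

    def test_score_non_decreasing_in_k(self):
        rng = np.random.default_rng(3)
        h = hist(rng.random(30))
        sets = optimal_thresholds_upto(h, 8)
        scores = [t.score for t in sets]
        assert all(b >= a - 1e-15 for a, b in zip(scores, scores[1:]))

    def test_k_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            optimal_thresholds(hist([1, 1, 1]), 3)

    def test_all_bins_separate_matches_closed_form(self):
        # k = n-1: every bin its own class, score = sum i^2 p_i
        h = hist([0.1, 0.2, 0.3, 0.4])
        T = brute_force_thresholds(h, 3)
        p = h.probabilities
        expect = (np.arange(1, 5) ** 2 * p).sum()
        assert T.score == pytest.approx(expect, rel=1e-12)
        assert optimal_thresholds(h, 3).score == pytest.approx(expect, rel=1e-12)

    def test_dp_equals_oracle_on_random_instances(self):
        """DP and exhaustive enumeration agree exactly (score bitwise,
        thresholds under the shared tie-break) on 200 random histograms."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 65))
            k = min(int(rng.integers(1, 5)), n - 1)
            m = np.where(rng.random(n) < 0.8, rng.random(n), 0.0)
            if m.sum() == 0:
                m[0] = 1.0
            h = hist(m)
            dp = optimal_thresholds(h, k)
            oracle = brute_force_thresholds(h, k)
            assert dp.score == oracle.score
            assert dp.thresholds == oracle.thresholds

    def test_oracle_budget_guard(self):
        with pytest.raises(ValueError):
            brute_force_thresholds(hist(np.ones(200)), 5, budget=1000)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=5, max_size=24).filter(
            lambda v: sum(v) > 0
        ),
        st.integers(1, 3),
    )
    def test_dp_dominates_any_valid_threshold_set(self, masses, k):
        h = hist(masses)
        k = min(k, h.n - 1)
        best = optimal_thresholds(h, k)
        rng = np.random.default_rng(42)
        for _ in range(5):
            cand = tuple(
                sorted(rng.choice(np.arange(1, h.n), size=k, replace=False))
            )
            T = ThresholdSet(thresholds=cand, score=0.0, n=h.n)
            assert between_class_score(h, T) <= best.score + 1e-12

    def test_moving_threshold_within_zero_run_keeps_score(self):
        h = hist([2, 3, 0, 0, 0, 4, 5])
        scores = {
            between_class_score(h, ThresholdSet(thresholds=(t,), score=0.0, n=7))
            for t in (2, 3, 4, 5)
        }
        assert len(scores) == 1  # any cut through the empty run is equivalent
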