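"""Platt scaling, rank-weighted Noisy-OR, reliable negatives, PU loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from pumil import pooling as P
from pumil.model import EPS_CLIP


def oracle_weighted_noisy_or(f):
    """Independent transcription of the rank-weighted Noisy-OR.

    Ascending ranks of the instance probabilities, normalized to [0, 1],
    two Gaussian-density peaks (mean 0 and 1, SD 0.1), weights normalized
    within bag, then F = 1 - prod (1 - f_j)^{w_j}.
    """
    f = np.asarray(f, dtype=float)
    k = len(f)
    if k == 1:
        w = np.array([1.0])
    else:
        order = sorted(range(k), key=lambda j: (f[j], j))
        rank = {j: r for r, j in enumerate(order)}
        u = np.array([rank[j] / (k - 1) for j in range(k)])
        S = np.array([norm.pdf(x, 0, 0.1) + norm.pdf(x, 1, 0.1) for x in u])
        w = S / S.sum()
    prod = 1.0
    for fj, wj in zip(f, w):
        prod *= max(1.0 - fj, EPS_CLIP) ** wj
    return 1.0 - prod, w


class TestPlatt:
    def test_zero_score_maps_to_half(self):
        assert P.platt(np.array([0.0]), P.PlattParams(1, 0))[0] == pytest.approx(0.5)

    def test_score_two_maps_to_0880797(self):
        f = P.platt(np.array([2.0]), P.PlattParams(1, 0))[0]
        assert f == pytest.approx(0.880797, abs=1e-6)

    def test_zero_alpha_is_constant(self):
        f = P.platt(np.array([-3.0, 0.0, 5.0]), P.PlattParams(0, 0.7))
        np.testing.assert_allclose(f, 1 / (1 + np.exp(-0.7)))

    def test_monotone_when_alpha_positive(self):
        atts = np.linspace(-4, 4, 9)
        f = P.platt(atts, P.PlattParams(2.0, -0.3))
        assert np.all(np.diff(f) > 0)


class TestRankWeights:
    def test_two_instances_split_evenly(self):
        w = P.rank_weights(np.array([0.1, 0.9]))
        np.testing.assert_allclose(w.weights, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(w.normalized_ranks, [0.0, 1.0])

    def test_singleton_convention(self):
        w = P.rank_weights(np.array([0.3]))
        np.testing.assert_allclose(w.weights, [1.0])

    def test_three_instance_frozen_values(self):
        # middle rank sits at u=0.5 where both Gaussian peaks are ~null
        w = P.rank_weights(np.array([0.2, 0.5, 0.8]))
        np.testing.assert_allclose(w.weights, [0.4999981, 3.727e-6, 0.4999981],
                                   atol=1e-6)
        assert w.weights[1] < 1e-3

    def test_ties_broken_by_index(self):
        w = P.rank_weights(np.array([0.5, 0.5, 0.5]))
        assert list(w.ranks) == [0, 1, 2]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=99))
    def test_weights_sum_to_one_and_peak_at_extremes(self, k, seed):
        f = np.random.default_rng(seed).uniform(size=k)
        w = P.rank_weights(f)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)
        if k >= 3:
            top = int(np.argmax(w.normalized_ranks))
            bottom = int(np.argmin(w.normalized_ranks))
            assert w.weights[top] == np.max(w.weights) or \
                   w.weights[bottom] == np.max(w.weights)


class TestNoisyOr:
    def test_all_zero_probabilities_give_zero(self):
        f = np.zeros(3)
        assert P.weighted_noisy_or(f, P.rank_weights(f).weights) == pytest.approx(0.0, abs=1e-6)
        assert P.standard_noisy_or(np.zeros(7)) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_two_instances(self):
        F = P.weighted_noisy_or(np.array([0.1, 0.9]), np.array([0.5, 0.5]))
        assert F == pytest.approx(1 - (0.9 * 0.1) ** 0.5, abs=1e-9)
        assert F == pytest.approx(0.7, abs=1e-6)

    def test_closed_form_three_instances(self):
        f = np.array([0.2, 0.5, 0.8])
        F = P.weighted_noisy_or(f, P.rank_weights(f).weights)
        assert F == pytest.approx(0.5999997, abs=1e-6)

    def test_standard_noisy_or_half_half(self):
        assert P.standard_noisy_or(np.array([0.5, 0.5])) == pytest.approx(0.75)

    def test_standard_noisy_or_saturates_with_depth(self):
        # the depth pathology motivating the weighted variant
        Fs = [P.standard_noisy_or(np.full(k, 0.1)) for k in (5, 20, 80)]
        assert Fs[0] < Fs[1] < Fs[2]
        assert Fs[2] > 0.999

    def test_weighted_variant_stable_with_depth(self):
        Fs = [P.bag_probability(np.full(k, 0.1)) for k in (5, 20, 80)]
        assert max(Fs) - min(Fs) < 0.05

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10 ** 6))
    def test_oracle_equivalence(self, k, seed):
        f = np.random.default_rng(seed).uniform(size=k)
        expect, w_expect = oracle_weighted_noisy_or(f)
        got = P.weighted_noisy_or(f, P.rank_weights(f).weights)
        assert got == pytest.approx(expect, abs=1e-10)
        np.testing.assert_allclose(P.rank_weights(f).weights, w_expect, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=5, max_value=30), st.integers(min_value=0, max_value=99))
    def test_middle_rank_weight_is_negligible(self, k, seed):
        f = np.random.default_rng(seed).uniform(size=k)
        w = P.rank_weights(f)
        middle = int(np.argmin(np.abs(w.normalized_ranks - 0.5)))
        assert w.weights[middle] < 1e-3

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=99))
    def test_bounded_and_monotone(self, k, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(size=k)
        w = P.rank_weights(f).weights
        F = P.weighted_noisy_or(f, w)
        assert 0.0 <= F <= 1.0
        j = int(rng.integers(k))
        f2 = f.copy()
        f2[j] = min(1.0, f2[j] + 0.05)
        assert P.weighted_noisy_or(f2, w) >= F - 1e-12

    def test_gradient_matches_finite_difference(self):
        f = np.array([0.2, 0.6, 0.4, 0.8])
        for variant in ("weighted_noisy_or", "noisy_or", "mean"):
            F, g = P.bag_probability_grad(f, variant)
            for j in range(len(f)):
                d = np.zeros_like(f)
                d[j] = 1e-7
                # weights held fixed across the perturbation for the ranked variant
                if variant == "weighted_noisy_or":
                    w = P.rank_weights(f).weights
                    fd = (P.weighted_noisy_or(f + d, w) - P.weighted_noisy_or(f - d, w)) / 2e-7
                else:
                    fd = (P.bag_probability(f + d, variant)
                          - P.bag_probability(f - d, variant)) / 2e-7
                assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestReliableNegatives:
    def test_selects_lowest_probabilities(self):
        probs = {"b1": 0.9, "b2": 0.1, "b3": 0.5, "b4": 0.2}
        assert P.select_reliable_negatives(probs, 2) == {"b2", "b4"}

    def test_all_unlabeled_when_counts_match(self):
        probs = {"a": 0.4, "b": 0.6}
        assert P.select_reliable_negatives(probs, 2) == {"a", "b"}

    def test_tie_break_is_deterministic(self):
        probs = {"z": 0.5, "a": 0.5, "m": 0.5, "k": 0.1}
        first = P.select_reliable_negatives(probs, 2)
        assert first == P.select_reliable_negatives(dict(reversed(list(probs.items()))), 2)
        assert first == {"k", "a"}  # bag_id order breaks the tie

    def test_too_few_unlabeled_errors(self):
        with pytest.raises(ValueError, match="unlabeled"):
            P.select_reliable_negatives({"a": 0.1}, 2)


class TestPuLoss:
    def test_frozen_value(self):
        got = P.loss_pu(np.array([0.8]), np.array([0.2]), P.PlattParams(0, 0), 0.0)
        assert got == pytest.approx(0.446287, abs=1e-6)

    def test_perfect_separation_near_zero(self):
        got = P.loss_pu(np.array([1 - 1e-7]), np.array([1e-7]),
                        P.PlattParams(0, 0), 0.0)
        assert got == pytest.approx(0.0, abs=1e-5)

    def test_penalty_arithmetic(self):
        base = P.loss_pu(np.array([0.8]), np.array([0.2]), P.PlattParams(2, 1), 0.0)
        with_pen = P.loss_pu(np.array([0.8]), np.array([0.2]), P.PlattParams(2, 1), 1.0)
        assert with_pen - base == pytest.approx(5.0, abs=1e-9)

    def test_unbalanced_sets_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            P.loss_pu(np.array([0.8, 0.9]), np.array([0.2]), P.PlattParams(0, 0), 0.0)


class TestTotalLoss:
    def test_sum_and_identity(self):
        assert P.total_loss(0.5, 0.25) == pytest.approx(0.75)
        assert P.total_loss(1.23, 0.0) == pytest.approx(1.23)
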