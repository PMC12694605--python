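"""Listwise losses (ApproxNDCG, ListNet), their combination, negative sampling."""

import math

import numpy as np
import pytest

from adjurank.objectives import (LossConfig, approx_ndcg_loss, combined_loss,
                                 listnet_loss, query_loss, sample_negatives,
                                 smooth_ranks)

from .oracles import brute_ndcg


class TestApproxNdcg:
    def test_tight_at_small_tau_on_ideal_order(self):
        g = np.array([2.0, 1.0, 1.0, 0.0])
        s = np.array([4.0, 3.0, 2.0, 1.0])  # strictly ordered, matches ideal
        assert approx_ndcg_loss(s, g, k=None, tau=1e-4) == pytest.approx(0.0, abs=1e-3)

    def test_tied_scores_smooth_ranks_and_gradient_signs(self):
        g = np.array([1.0, 0.0])
        s = np.array([0.0, 0.0])
        np.testing.assert_allclose(smooth_ranks(s, 1.0), [1.5, 1.5])
        loss, grad = approx_ndcg_loss(s, g, k=None, tau=1.0, return_grad=True)
        assert np.isfinite(loss)
        assert grad[0] < 0 < grad[1]  # descent pushes s1 up, s2 down

    @pytest.mark.parametrize("seed", range(50))
    def test_small_tau_equals_one_minus_exact_ndcg(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        g = rng.integers(0, 3, n).astype(float)
        if g.sum() == 0:
            g[0] = 1.0
        s = rng.normal(size=n)
        while np.min(np.diff(np.sort(s))) < 0.05:  # well-separated scores
            s = rng.normal(size=n)
        k = int(rng.integers(1, n + 1))
        expected = 1.0 - brute_ndcg(list(g[np.argsort(-s, kind="stable")]), k)
        assert approx_ndcg_loss(s, g, k=k, tau=1e-4) == pytest.approx(expected, abs=1e-3)

    def test_all_zero_gains_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            approx_ndcg_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        g = np.array([2.0, 0.0, 1.0, 0.0])
        s = rng.normal(size=4)
        perm = rng.permutation(4)
        assert approx_ndcg_loss(s, g, k=2, tau=0.5) == \
            pytest.approx(approx_ndcg_loss(s[perm], g[perm], k=2, tau=0.5), abs=1e-12)


class TestListNet:
    def test_hand_example_is_ln2(self):
        assert listnet_loss(np.array([0.0, 0.0]), np.array([1.0, 0.0])) == \
            pytest.approx(math.log(2.0), abs=1e-12)

    def test_scores_equal_gains_attain_minimum_entropy(self):
        g = np.array([2.0, 1.0, 0.0])
        p = np.exp(g) / np.exp(g).sum()
        entropy = -np.sum(p * np.log(p))
        assert listnet_loss(g.copy(), g) == pytest.approx(entropy, abs=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert listnet_loss(rng.normal(size=3), g) >= entropy - 1e-12

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        s, g = rng.normal(size=5), rng.integers(0, 3, 5).astype(float)
        assert listnet_loss(s + 17.3, g) == pytest.approx(listnet_loss(s, g), abs=1e-9)

    def test_all_zero_gains_give_uniform_target(self):
        loss = listnet_loss(np.zeros(4), np.zeros(4))
        assert loss == pytest.approx(math.log(4.0))


class TestCombined:
    def test_mixture_endpoints_match_components(self):
        rng = np.random.default_rng(0)
        s, g = rng.normal(size=5), np.array([2.0, 1.0, 0.0, 0.0, 1.0])
        pure_a = query_loss(s, g, LossConfig(tau=0.3, mix_w=1.0, ndcg_k=3))
        pure_l = query_loss(s, g, LossConfig(tau=0.3, mix_w=0.0, ndcg_k=3))
        assert pure_a == approx_ndcg_loss(s, g, k=3, tau=0.3)
        assert pure_l == listnet_loss(s, g)

    def test_lambda_penalty_is_additive(self):
        rng = np.random.default_rng(1)
        batch = [(rng.normal(size=4), np.array([1.0, 0.0, 2.0, 0.0]))]
        l2 = 3.7
        l0 = combined_loss(batch, l2, LossConfig(lam=0.0))
        l1 = combined_loss(batch, l2, LossConfig(lam=0.01))
        l2x = combined_loss(batch, l2, LossConfig(lam=0.02))
        assert l1 - l0 == pytest.approx(0.01 * 3.7)
        assert l2x - l0 == pytest.approx(0.02 * 3.7)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            combined_loss([], 0.0, LossConfig())

    @pytest.mark.parametrize("w", [0.0, 0.25, 0.5, 1.0])
    def test_gradient_step_separates_two_candidates(self, w):
        g = np.array([1.0, 0.0])
        s = np.array([0.0, 0.0])
        _, grad = query_loss(s, g, LossConfig(tau=1.0, mix_w=w, ndcg_k=2),
                             return_grad=True)
        s2 = s - 0.1 * grad
        assert s2[0] - s2[1] > 0


class TestSampleNegatives:
    adjuvants = [f"a{i}" for i in range(10)]

    def test_exhaustion_returns_every_non_positive(self):
        out = sample_negatives(self.adjuvants, {"a0", "a1"}, n_neg=50,
                               rng=np.random.default_rng(0))
        assert sorted(out) == sorted(set(self.adjuvants) - {"a0", "a1"})

    def test_reproducible_given_seed(self):
        a = sample_negatives(self.adjuvants, {"a0"}, 3, np.random.default_rng(42))
        b = sample_negatives(self.adjuvants, {"a0"}, 3, np.random.default_rng(42))
        assert a == b

    def test_all_positive_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            sample_negatives(["a0"], {"a0"}, 1, np.random.default_rng(0))

    def test_uniform_within_binomial_bounds(self):
        rng = np.random.default_rng(7)
        pool = sorted(set(self.adjuvants) - {"a0"})
        counts = {a: 0 for a in pool}
        n_draws = 10_000
        for _ in range(n_draws):
            counts[sample_negatives(self.adjuvants, {"a0"}, 1, rng)[0]] += 1
        p = 1 / len(pool)
        sigma = math.sqrt(n_draws * p * (1 - p))
        for a, c in counts.items():
            assert abs(c - n_draws * p) < 3 * sigma, a


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(tau=0.0)
    with pytest.raises(ValueError):
        LossConfig(mix_w=1.5)
    with pytest.raises(ValueError):
        LossConfig(n_neg=0)
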