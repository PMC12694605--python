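"""Graded-relevance metrics vs brute-force oracles; calibration; rank swap."""

import numpy as np
import pandas as pd
import pytest

from adjurank.metrics import (dcg_at_k, dcg_curves, macro_average, ndcg_at_k,
                              precision_at_k, rank_swap, recall_at_k,
                              reliability_and_ece)

from .oracles import brute_dcg, brute_ndcg, brute_precision, brute_recall


class TestWorkedValues:
    def test_dcg_hand_value(self):
        assert dcg_at_k([2, 1, 0], 3) == pytest.approx(2.63093, abs=1e-5)

    def test_dcg_all_zero(self):
        assert dcg_at_k([0, 0, 0], 3) == 0.0

    def test_dcg_at_one_is_first_gain(self):
        assert dcg_at_k([2, 1, 0], 1) == 2.0

    def test_ndcg_hand_value(self):
        assert ndcg_at_k([1, 2], 2) == pytest.approx(0.85972, abs=1e-5)

    def test_ndcg_ideal_order_is_one(self):
        assert ndcg_at_k([2, 2, 1, 0, 0], 3) == 1.0

    def test_recall_hand_value(self):
        assert recall_at_k([2, 0, 1, 0, 1], 2) == pytest.approx(1 / 3)

    def test_precision_four_of_five(self):
        assert precision_at_k([2, 1, 1, 0, 2, 0], 5) == pytest.approx(0.80)

    def test_precision_exact_only_switch(self):
        assert precision_at_k([2, 1, 1, 0, 2], 5, exact_only=True) == pytest.approx(0.4)

    def test_precision_none_and_top1(self):
        assert precision_at_k([0, 0, 2], 2) == 0.0
        assert precision_at_k([1, 0], 1) == 1.0


@pytest.mark.parametrize("seed", range(40))
def test_metrics_match_brute_force_oracles(seed):
    """5 random instances per seed: 200 total, lengths <= 8, gains in {0,1,2}."""
    rng = np.random.default_rng(seed)
    for _ in range(5):
        n = int(rng.integers(1, 9))
        g = rng.integers(0, 3, n)
        if g.sum() == 0:
            g[rng.integers(0, n)] = rng.integers(1, 3)
        g = list(map(int, g))
        k = int(rng.integers(1, 10))
        assert abs(dcg_at_k(g, k) - brute_dcg(g, k)) < 1e-10
        assert abs(ndcg_at_k(g, k) - brute_ndcg(g, k)) < 1e-10
        assert abs(recall_at_k(g, k) - brute_recall(g, k)) < 1e-10
        assert abs(precision_at_k(g, k) - brute_precision(g, k)) < 1e-10
        assert 0.0 <= ndcg_at_k(g, k) <= 1.0


def test_recall_monotone_in_k():
    g = [0, 2, 0, 1, 0, 1]
    vals = [recall_at_k(g, k) for k in range(1, 7)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))
    assert vals[-1] == 1.0


def test_ndcg_requires_a_positive_gain():
    with pytest.raises(ValueError):
        ndcg_at_k([0, 0], 2)


class TestMacroAverage:
    def test_single_disease_identity(self):
        df = pd.DataFrame({"disease_id": ["d"], "ndcg@10": [0.4]})
        assert macro_average(df)["ndcg@10"] == 0.4

    def test_unweighted_and_order_invariant(self):
        df = pd.DataFrame({"disease_id": ["d1", "d2"], "ndcg@10": [0.2, 0.8]})
        assert macro_average(df)["ndcg@10"] == pytest.approx(0.5)
        assert macro_average(df.iloc[::-1])["ndcg@10"] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            macro_average(pd.DataFrame(columns=["disease_id", "x"]))


class TestReliability:
    def test_hand_built_two_bin_example(self):
        # bin1: two items conf 0.2 prec 0.5; bin2: two items conf 0.9 prec 0.5
        from scipy.special import logit
        scores = logit(np.array([0.2, 0.2, 0.9, 0.9]))
        rel = np.array([1.0, 0.0, 1.0, 0.0])
        bins, ece = reliability_and_ece(scores, rel, n_bins=2)
        assert ece == pytest.approx(0.35, abs=1e-12)
        assert len(bins) == 2
        assert bins["precision"].tolist() == [0.5, 0.5]

    def test_perfectly_calibrated_bins(self):
        from scipy.special import logit
        scores = logit(np.array([0.25, 0.25, 0.25, 0.25, 0.75, 0.75, 0.75, 0.75]))
        rel = np.array([1, 0, 0, 0, 1, 1, 1, 0], dtype=float)
        _, ece = reliability_and_ece(scores, rel, n_bins=2)
        assert ece == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_ece_bounded(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30) * 3
        rel = rng.integers(0, 2, 30).astype(float)
        _, ece = reliability_and_ece(scores, rel)
        assert 0.0 <= ece <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reliability_and_ece(np.array([]), np.array([]))


class TestRankSwap:
    def test_identical_rankings_all_zero(self):
        df = rank_swap(["a", "b", "c"], ["a", "b", "c"])
        assert (df["delta"] == 0).all()

    def test_promotion_by_six_positions(self):
        full = ["x1", "x2", "cpg", "x3", "x4", "x5", "x6", "x7", "x8"]
        ablated = ["x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "cpg"]
        df = rank_swap(full, ablated)
        row = df[df["candidate"] == "cpg"].iloc[0]
        assert row["rank_full"] == 3 and row["rank_ablated"] == 9
        assert row["delta"] == 6
        assert df.iloc[0]["candidate"] == "cpg"  # sorted by |delta| desc

    def test_deltas_sum_to_zero(self):
        rng = np.random.default_rng(0)
        ids = [f"a{i}" for i in range(12)]
        df = rank_swap(list(rng.permutation(ids)), list(rng.permutation(ids)))
        assert df["delta"].sum() == 0

    def test_candidate_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="zz"):
            rank_swap(["a", "zz"], ["a", "b"])


def test_dcg_curves_monotone_and_end_equal():
    g = [0, 2, 1, 0, 1]
    df = dcg_curves(g)
    assert (df["idcg"] >= df["dcg"] - 1e-12).all()
    assert df["dcg"].iloc[-1] == pytest.approx(dcg_at_k(g, 5))
    assert df["idcg"].iloc[-1] == pytest.approx(dcg_at_k(sorted(g, reverse=True), 5))
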