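"""Bilinear + mechanism-prior scoring and deterministic ranking."""

import numpy as np
import pytest
from scipy.special import expit

from adjurank.objectives import LossConfig
from adjurank.scorer import (RankerParams, mechanism_match, rank_candidates,
                             score, score_candidates)
from adjurank.train import _query_grads


def params_with(W=None, Wm=None, gamma=0.0, dim=2, P=2):
    return RankerParams(W_f=np.eye(dim), b_f=np.zeros(dim),
                        W=np.zeros((dim, dim)) if W is None else W,
                        Wm=np.zeros((P, dim)) if Wm is None else Wm,
                        gamma=gamma)


class TestMechanismMatch:
    def test_zero_cue_vector_is_neutral(self):
        rng = np.random.default_rng(0)
        Wm = rng.normal(size=(3, 4))
        assert mechanism_match(rng.normal(size=4), np.zeros(3), Wm) == 0.5

    def test_saturates_to_one(self):
        Wm = np.array([[50.0]])
        assert mechanism_match(np.array([1.0]), np.array([1.0]), Wm) == \
            pytest.approx(1.0, abs=1e-9)

    def test_hand_dot_product(self):
        # Wm h_d = [1, -1], phi = [1, 1] -> sigmoid(0) = 0.5
        Wm = np.array([[1.0, 0.0], [0.0, -1.0]])
        assert mechanism_match(np.array([1.0, 1.0]), np.array([1.0, 1.0]), Wm) == 0.5

    def test_always_in_open_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = mechanism_match(rng.normal(size=3), rng.integers(0, 2, 4).astype(float),
                                rng.normal(size=(4, 3)))
            assert 0.0 < m < 1.0


class TestScore:
    def test_gamma_zero_is_pure_bilinear(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 3))
        p = params_with(W=W, Wm=rng.normal(size=(2, 3)), gamma=0.0, dim=3, P=2)
        h_d, h_a = rng.normal(size=3), rng.normal(size=3)
        assert score(h_d, h_a, np.ones(2), p) == pytest.approx(h_d @ W @ h_a)

    def test_hand_bilinear_evaluation(self):
        W = np.zeros((3, 3))
        W[0, 1] = 3.0
        p = params_with(W=W, dim=3, P=1, Wm=np.zeros((1, 3)))
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert score(e1, e2, np.zeros(1), p) == 3.0

    def test_zero_cues_add_half_gamma(self):
        W = np.zeros((3, 3))
        W[0, 1] = 3.0
        p = params_with(W=W, dim=3, P=1, Wm=np.zeros((1, 3)), gamma=2.0)
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert score(e1, e2, np.zeros(1), p) == pytest.approx(3.0 + 1.0)

    def test_monotone_in_gamma(self):
        rng = np.random.default_rng(2)
        h_d, h_a = rng.normal(size=3), rng.normal(size=3)
        phi = np.array([1.0, 0.0])
        Wm = rng.normal(size=(2, 3))
        W = rng.normal(size=(3, 3))
        scores = [score(h_d, h_a, phi,
                        params_with(W=W, Wm=Wm, gamma=g, dim=3, P=2))
                  for g in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(scores) > 0)  # m > 0 always

    def test_identity_w_orthonormal_frame_is_dot_product(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        p = params_with(W=np.eye(4), dim=4, P=1, Wm=np.zeros((1, 4)))
        for i in range(4):
            for j in range(4):
                s = score(Q[:, i], Q[:, j], np.zeros(1), p)
                assert s == pytest.approx(float(i == j), abs=1e-12)


class TestRanking:
    def test_sorts_descending(self):
        ranked = rank_candidates(["a", "b", "c"], np.array([2.0, 1.0, 3.0]))
        assert [r[0] for r in ranked] == ["c", "a", "b"]

    def test_ties_break_by_id_ascending(self):
        ranked = rank_candidates(["b", "c", "a"], np.array([1.0, 1.0, 1.0]))
        assert [r[0] for r in ranked] == ["a", "b", "c"]

    def test_input_order_irrelevant(self):
        ids = ["a", "b", "c", "d"]
        s = {"a": 0.3, "b": 0.1, "c": 0.3, "d": 0.9}
        ref = rank_candidates(ids, np.array([s[i] for i in ids]))
        perm = ["d", "a", "c", "b"]
        out = rank_candidates(perm, np.array([s[i] for i in perm]))
        assert [r[0] for r in out] == [r[0] for r in ref]


def test_query_gradients_match_finite_differences():
    """d(loss)/d(W_f, b_f, W, Wm) against central differences, and d(score)/d(gamma)."""
    rng = np.random.default_rng(0)
    n, d_in, dim, P = 5, 6, 4, 3
    x_d = rng.normal(size=d_in)
    Xa = rng.normal(size=(n, d_in))
    Phi = rng.integers(0, 2, (n, P)).astype(float)
    g = np.array([2.0, 1.0, 0.0, 0.0, 1.0])
    params = RankerParams.init(d_in, dim, P, rng, gamma=1.3)
    lc = LossConfig(tau=0.7, mix_w=0.5, n_neg=2, lam=0.0, ndcg_k=3)

    _, grads = _query_grads(x_d, Xa, Phi, g, params, lc)
    eps = 1e-6
    for name in ("W_f", "b_f", "W", "Wm"):
        arr = getattr(params, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + eps
            lp, _ = _query_grads(x_d, Xa, Phi, g, params, lc)
            arr[ix] = orig - eps
            lm, _ = _query_grads(x_d, Xa, Phi, g, params, lc)
            arr[ix] = orig
            fd = (lp - lm) / (2 * eps)
            assert fd == pytest.approx(grads[name][ix], rel=1e-4, abs=1e-8), (name, ix)

    # gamma enters the score linearly through m: ds/dgamma = m
    h_d = x_d @ params.W_f + params.b_f
    Ha = Xa @ params.W_f + params.b_f
    m = expit(Phi @ (params.Wm @ h_d))
    s1 = score_candidates(h_d, Ha, Phi, params)
    params2 = RankerParams(**{**params.trainable(), "gamma": params.gamma + eps,
                              "lam": params.lam})
    s2 = score_candidates(h_d, Ha, Phi, params2)
    np.testing.assert_allclose((s2 - s1) / eps, m, rtol=1e-5)


def test_params_validation():
    with pytest.raises(ValueError, match="gamma"):
        params_with(gamma=-0.1)
    with pytest.raises(ValueError, match="non-finite"):
        RankerParams(W_f=np.array([[np.nan]]), b_f=np.zeros(1),
                     W=np.zeros((1, 1)), Wm=np.zeros((1, 1)))
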