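"""Listwise training losses and negative sampling.

Two surrogates are combined per query (disease):

* **ApproxNDCG** — a smooth NDCG surrogate.  The hard rank of candidate i is
  replaced by the smooth rank

      r_i = 1 + sum_{j != i} sigmoid((s_j - s_i) / tau),

  which recovers the true 1-based rank as tau -> 0 (ties land halfway).  The
  surrogate DCG discounts each gain by log2(r_i + 1) and gates it with a
  smooth top-k indicator sigmoid((k + 1/2 - r_i) / tau); dividing by the exact
  (score-independent) IDCG@k gives a differentiable NDCG whose tau -> 0 limit
  is the exact metric.  The loss is 1 minus that quantity.

* **ListNet** (top-1 variant) — cross-entropy between the softmax of the
  gains and the softmax of the scores.

The per-query loss is w * ApproxNDCG + (1 - w) * ListNet; the batch objective
adds an L2 penalty lam * ||theta||^2 over the trainable weights.  Every loss
here returns both the value and its gradient with respect to the scores, so
training needs no autodiff framework — the scorer is bilinear, and the chain
rule to its parameters is closed-form (see train.py).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax

LOG2 = np.log(2.0)


@dataclass(frozen=True)
class LossConfig:
    """Hybrid-loss settings: temperature, mixture weight, sampling, L2."""

    tau: float = 1.0
    mix_w: float = 0.5
    n_neg: int = 20
    lam: float = 1e-4
    ndcg_k: int | None = 10

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.mix_w <= 1.0:
            raise ValueError(f"mix_w must be in [0,1], got {self.mix_w}")
        if self.n_neg < 1:
            raise ValueError(f"n_neg must be >= 1, got {self.n_neg}")


def _check_lists(s: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(s, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if s.shape != g.shape or s.ndim != 1 or s.shape[0] < 2:
        raise ValueError(f"scores and gains must be equal-length vectors (>=2): {s.shape} vs {g.shape}")
    return s, g


def smooth_ranks(s: np.ndarray, tau: float) -> np.ndarray:
    """r_i = 1 + sum_{j!=i} sigmoid((s_j - s_i)/tau); exact ranks as tau -> 0."""
    diff = (s[None, :] - s[:, None]) / tau  # diff[i, j] = (s_j - s_i)/tau
    sig = expit(diff)
    np.fill_diagonal(sig, 0.0)
    return 1.0 + sig.sum(axis=1)


def ideal_dcg(g: np.ndarray, k: int | None) -> float:
    g_sorted = np.sort(g)[::-1]
    if k is not None:
        g_sorted = g_sorted[:k]
    ranks = np.arange(1, g_sorted.shape[0] + 1)
    return float(np.sum(g_sorted / np.log2(ranks + 1)))


def approx_ndcg_loss(
    s: np.ndarray,
    g: np.ndarray,
    k: int | None = None,
    tau: float = 1.0,
    return_grad: bool = False,
):
    """Smooth 1 - NDCG@k.  ``k=None`` scores the full list (no gate).

    Raises if every gain is zero (such queries must be filtered upstream:
    the ideal DCG would vanish).  With ``return_grad`` also returns dloss/ds.
    """
    s, g = _check_lists(s, g)
    idcg = ideal_dcg(g, k)
    if idcg == 0.0:
        raise ValueError("approx_ndcg_loss: all gains are zero (IDCG=0)")

    r = smooth_ranks(s, tau)
    discount = 1.0 / np.log2(r + 1.0)
    if k is None:
        gate = np.ones_like(r)
        dgate_dr = np.zeros_like(r)
    else:
        u = (k + 0.5 - r) / tau
        gate = expit(u)
        dgate_dr = -gate * (1.0 - gate) / tau
    loss = 1.0 - float(np.sum(g * gate * discount)) / idcg
    if not return_grad:
        return loss

    # d discount / d r = -1 / ((r+1) ln2 log2(r+1)^2)
    ddisc_dr = -1.0 / ((r + 1.0) * LOG2 * np.log2(r + 1.0) ** 2)
    dloss_dr = -(g / idcg) * (gate * ddisc_dr + discount * dgate_dr)
    # dr_i/ds_j = sig'_{ij}/tau (j != i); dr_i/ds_i = -sum_j sig'_{ij}/tau
    diff = (s[None, :] - s[:, None]) / tau
    sigp = expit(diff)
    sigp = sigp * (1.0 - sigp) / tau  # symmetric since sigmoid' is even
    np.fill_diagonal(sigp, 0.0)
    grad = sigp.T @ dloss_dr - dloss_dr * sigp.sum(axis=1)
    return loss, grad


def listnet_loss(s: np.ndarray, g: np.ndarray, return_grad: bool = False):
    """Top-1 ListNet: cross-entropy(softmax(g), softmax(s)).

    All-zero gains are legal (uniform target).  Invariant to a constant shift
    of the scores.
    """
    s, g = _check_lists(s, g)
    p = softmax(g)
    log_q = s - (np.max(s) + np.log(np.sum(np.exp(s - np.max(s)))))
    loss = float(-np.sum(p * log_q))
    if not return_grad:
        return loss
    return loss, np.exp(log_q) - p


def query_loss(s: np.ndarray, g: np.ndarray, cfg: LossConfig, return_grad: bool = False):
    """Per-query hybrid loss w*ApproxNDCG + (1-w)*ListNet (and d/ds)."""
    w = cfg.mix_w
    if return_grad:
        grad = np.zeros_like(np.asarray(s, dtype=np.float64))
        loss = 0.0
        if w > 0:
            l1, g1 = approx_ndcg_loss(s, g, k=cfg.ndcg_k, tau=cfg.tau, return_grad=True)
            loss += w * l1
            grad += w * g1
        if w < 1:
            l2, g2 = listnet_loss(s, g, return_grad=True)
            loss += (1 - w) * l2
            grad += (1 - w) * g2
        return loss, grad
    loss = 0.0
    if w > 0:
        loss += w * approx_ndcg_loss(s, g, k=cfg.ndcg_k, tau=cfg.tau)
    if w < 1:
        loss += (1 - w) * listnet_loss(s, g)
    return loss


def combined_loss(per_query: list[tuple[np.ndarray, np.ndarray]], l2_sq: float, cfg: LossConfig) -> float:
    """Batch objective: sum of per-query hybrid losses + lam * ||theta||^2."""
    if not per_query:
        raise ValueError("empty batch")
    return sum(query_loss(s, g, cfg) for s, g in per_query) + cfg.lam * l2_sq


def sample_negatives(
    all_adjuvants: list[str],
    positives_of_d,
    n_neg: int,
    rng: np.random.Generator,
) -> list[str]:
    """Uniform sample without replacement from the non-positive adjuvants.

    Returns all of them when fewer than ``n_neg`` exist; errors if the
    disease's positives exhaust the candidate set.
    """
    pool = [a for a in all_adjuvants if a not in positives_of_d]
    if not pool:
        raise ValueError("disease has no non-positive adjuvants to sample from")
    if len(pool) <= n_neg:
        return list(pool)
    idx = rng.choice(len(pool), size=n_neg, replace=False)
    return [pool[i] for i in sorted(idx)]
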