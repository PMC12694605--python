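"""Listwise training of the ranker with hand-derived gradients and Adam.

The scorer is bilinear in its parameters, so all gradients are closed-form:
for one query with propagated feature rows x_d (disease) and X_A (candidate
adjuvants), embeddings h = x W_f + b_f, scores

    s_i = h_d' W h_a_i + gamma * sigmoid((Wm h_d)' phi_i),

and an upstream gradient e = dL/ds from the listwise loss, the parameter
gradients follow from the chain rule (outer products with the feature rows).
Optimization is mini-batch Adam over query batches; negatives are resampled
every epoch; gamma is selected on a validation NDCG@10 grid.  All randomness
(init, shuffling, sampling) flows from one root seed split into named
substreams, so identical config + seed reproduces checkpoints bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .metrics import ndcg_at_k
from .model import ModelConfig, RankingPipeline
from .kg import QuerySet
from .objectives import LossConfig, query_loss, sample_negatives
from .scorer import RankerParams, order_by_score

logger = logging.getLogger(__name__)


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _query_grads(
    x_d: np.ndarray,
    Xa: np.ndarray,
    Phi: np.ndarray,
    gains: np.ndarray,
    params: RankerParams,
    loss_cfg: LossConfig,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and parameter gradients for one query (no regularization)."""
    h_d = x_d @ params.W_f + params.b_f
    Ha = Xa @ params.W_f + params.b_f
    u = params.Wm @ h_d
    t = Phi @ u
    m = expit(t)
    s = (h_d @ params.W) @ Ha.T + params.gamma * m
    loss, e = query_loss(s, gains, loss_cfg, return_grad=True)

    eh = e @ Ha  # sum_i e_i h_a_i
    gW = np.outer(h_d, eh)
    cm = params.gamma * e * m * (1.0 - m)
    gu = Phi.T @ cm
    gWm = np.outer(gu, h_d)
    gh_d = params.W @ eh + params.Wm.T @ gu
    gHa = np.outer(e, h_d @ params.W)
    gW_f = np.outer(x_d, gh_d) + Xa.T @ gHa
    gb_f = gh_d + gHa.sum(axis=0)
    return loss, {"W_f": gW_f, "b_f": gb_f, "W": gW, "Wm": gWm}


@dataclass
class TrainResult:
    params: RankerParams
    history: dict
    val_ndcg: float


def _val_ndcg(pipeline: RankingPipeline, queries: QuerySet, diseases: list[str],
              params: RankerParams, k: int, cold: bool = False) -> float:
    """Mean NDCG@k over diseases; ``cold`` scores each disease from its raw
    (unpropagated) features, i.e. as if it were unseen."""
    from .scorer import score_candidates

    vals = []
    for d in diseases:
        if cold:
            x_d = pipeline.features.X[pipeline.graph.index_of(d)]
            h_d = x_d @ params.W_f + params.b_f
            Ha = pipeline.X_adjuvants @ params.W_f + params.b_f
            s = score_candidates(h_d, Ha, pipeline.cues.Phi, params)
        else:
            s = pipeline.scores_for(d, params)
        order = order_by_score(queries.candidates, s)
        vals.append(ndcg_at_k(queries.gains[d][order], k))
    return float(np.mean(vals))


def train_once(
    pipeline: RankingPipeline,
    queries: QuerySet,
    train_diseases: list[str],
    val_diseases: list[str],
    cfg: ModelConfig,
    gamma: float,
    seed: np.random.SeedSequence,
) -> TrainResult:
    """Train all weights for one fixed gamma."""
    ss_init, ss_neg, ss_cold = seed.spawn(3)
    rng_init = np.random.default_rng(ss_init)
    rng_neg = np.random.default_rng(ss_neg)
    rng_cold = np.random.default_rng(ss_cold)

    params = RankerParams.init(cfg.d_in, cfg.dim, len(cfg.pathway_vocab), rng_init,
                               gamma=gamma, lam=cfg.lam)
    loss_cfg = LossConfig(tau=cfg.tau, mix_w=cfg.mix_w, n_neg=cfg.n_neg,
                          lam=cfg.lam, ndcg_k=cfg.ndcg_k)
    weights = params.trainable()
    opt = _Adam({k: v.shape for k, v in weights.items()}, cfg.lr)
    cand_index = {a: i for i, a in enumerate(queries.candidates)}
    Xadj, Phi = pipeline.X_adjuvants, pipeline.cues.Phi

    epoch_losses = []
    for epoch in range(cfg.epochs):
        order = list(train_diseases)
        rng_neg.shuffle(order)
        total = 0.0
        for start in range(0, len(order), cfg.batch_queries):
            batch = order[start:start + cfg.batch_queries]
            grads = {k: np.zeros_like(v) for k, v in weights.items()}
            batch_loss = 0.0
            for d in batch:
                pos = sorted(queries.positives[d])
                negs = sample_negatives(queries.candidates, queries.positives[d],
                                        cfg.n_neg, rng_neg)
                cand = pos + negs
                idx = np.array([cand_index[a] for a in cand])
                g = queries.gains[d][idx].astype(np.float64)
                if cfg.binary_gains:
                    g = (g >= 2).astype(np.float64)
                # Cold-start augmentation: with probability cold_start_p score
                # the query from the disease's raw features, exactly how an
                # unseen disease is scored at inference (node removed from
                # the graph = self-loop-only propagation).
                if rng_cold.random() < cfg.cold_start_p:
                    x_d = pipeline.features.X[pipeline.graph.index_of(d)]
                else:
                    x_d = pipeline.x_node(d)
                try:
                    loss, gq = _query_grads(x_d, Xadj[idx], Phi[idx],
                                            g, params, loss_cfg)
                except ValueError as exc:
                    raise ValueError(f"query {d!r}: {exc}") from exc
                batch_loss += loss
                for k in grads:
                    grads[k] += gq[k]
            # L2 on the weight matrices (bias excluded), as in the batch objective
            grads["W_f"] += 2 * cfg.lam * weights["W_f"]
            grads["W"] += 2 * cfg.lam * weights["W"]
            grads["Wm"] += 2 * cfg.lam * weights["Wm"]
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (gamma={gamma}); "
                    "lower lr or tau"
                )
            opt.step(weights, grads)
            total += batch_loss
        epoch_losses.append(total)

    # gamma/model selection targets zero-shot generalization: validation
    # queries are scored cold (raw disease features), matching inductive use.
    val = (_val_ndcg(pipeline, queries, val_diseases, params, cfg.ndcg_k, cold=True)
           if val_diseases else float("nan"))
    return TrainResult(params=params, history={"epoch_loss": epoch_losses}, val_ndcg=val)


def fit(
    pipeline: RankingPipeline,
    queries: QuerySet,
    train_diseases: list[str],
    cfg: ModelConfig,
    seed: int,
    gamma: float | None = None,
) -> TrainResult:
    """Train the ranker; tune gamma on a held-out validation grid.

    A deterministic ``val_fraction`` subset of the training diseases is held
    out of the training queries entirely and scored *cold* (raw features, as
    an unseen disease would be) — the grid therefore selects the gamma that
    generalizes, not the one that best memorizes.  Passing ``gamma`` skips
    the grid (used by ablations so they share the full model's gamma).
    """
    train_diseases = [d for d in train_diseases if d in queries.gains]
    if not train_diseases:
        raise ValueError("no trainable diseases (every one lacks positives?)")
    root = np.random.SeedSequence(seed)
    ss_split, ss_grid = root.spawn(2)
    rng = np.random.default_rng(ss_split)
    shuffled = list(train_diseases)
    rng.shuffle(shuffled)
    n_val = max(1, int(round(cfg.val_fraction * len(shuffled))))
    if n_val >= len(shuffled):
        n_val = len(shuffled) - 1
    val_diseases = sorted(shuffled[:n_val])
    train_diseases = sorted(shuffled[n_val:])

    grid = [gamma] if gamma is not None else list(cfg.gamma_grid)
    gamma_seeds = ss_grid.spawn(len(grid))
    best: TrainResult | None = None
    grid_scores: dict[str, float] = {}
    for gm, gseed in zip(grid, gamma_seeds):
        res = train_once(pipeline, queries, train_diseases, val_diseases, cfg, gm, gseed)
        grid_scores[repr(gm)] = res.val_ndcg
        logger.info("gamma=%.3g: validation NDCG@%d = %.4f", gm, cfg.ndcg_k, res.val_ndcg)
        if best is None or res.val_ndcg > best.val_ndcg + 1e-12:
            best = res
    assert best is not None
    best.history["gamma_grid_val_ndcg"] = grid_scores
    best.history["selected_gamma"] = best.params.gamma
    best.history["val_diseases"] = val_diseases
    return best
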