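"""Graded-relevance ranking metrics, calibration, and rank-swap analysis.

All metrics take the gain vector *in predicted order* (``g_ranked[i]`` is the
graded gain of the item the ranker placed at 1-based rank i+1) and a depth k.
Gains are graded {2, 1, 0}: exact known disease-adjuvant pair, correct
functional class, unrelated.  DCG uses the standard log2(i+1) discount;
NDCG normalizes by the ideal DCG of the *full* candidate list truncated at k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit


def dcg_at_k(g_ranked: np.ndarray, k: int) -> float:
    """DCG@k = sum_{i<=k} g_i / log2(i + 1), 1-based ranks."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    g = np.asarray(g_ranked, dtype=np.float64)[:k]
    ranks = np.arange(1, g.shape[0] + 1)
    return float(np.sum(g / np.log2(ranks + 1)))


def ndcg_at_k(g_ranked: np.ndarray, k: int) -> float:
    """DCG@k normalized by the ideal DCG@k over the full candidate list."""
    g = np.asarray(g_ranked, dtype=np.float64)
    idcg = dcg_at_k(np.sort(g)[::-1], k)
    if idcg == 0.0:
        raise ValueError("ndcg_at_k undefined: no positive gain in the candidate list")
    return dcg_at_k(g, k) / idcg


def recall_at_k(g_ranked: np.ndarray, k: int) -> float:
    """Fraction of relevant items (gain > 0) retrieved in the top k."""
    g = np.asarray(g_ranked, dtype=np.float64)
    n_rel = int(np.sum(g > 0))
    if n_rel == 0:
        raise ValueError("recall_at_k undefined: no relevant item in the candidate list")
    return float(np.sum(g[:k] > 0)) / n_rel


def precision_at_k(g_ranked: np.ndarray, k: int, exact_only: bool = False) -> float:
    """Fraction of the top k that are relevant.

    Relevant means gain > 0 by default (same threshold as recall); with
    ``exact_only`` only exact positives (gain >= 2) count.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    g = np.asarray(g_ranked, dtype=np.float64)[:k]
    thresh = 2.0 if exact_only else 1.0
    return float(np.sum(g >= thresh)) / k


def macro_average(per_disease: pd.DataFrame, metric_cols: list[str] | None = None) -> pd.Series:
    """Unweighted arithmetic mean over diseases (each disease = one query)."""
    if len(per_disease) == 0:
        raise ValueError("macro_average of an empty table")
    cols = metric_cols or [c for c in per_disease.columns if c != "disease_id"]
    return per_disease[cols].mean(axis=0)


def dcg_curves(g_ranked: np.ndarray) -> pd.DataFrame:
    """Cumulative DCG and IDCG by rank (for case-study gain curves)."""
    g = np.asarray(g_ranked, dtype=np.float64)
    disc = 1.0 / np.log2(np.arange(1, g.shape[0] + 1) + 1)
    return pd.DataFrame(
        {
            "rank": np.arange(1, g.shape[0] + 1),
            "dcg": np.cumsum(g * disc),
            "idcg": np.cumsum(np.sort(g)[::-1] * disc),
        }
    )


def reliability_and_ece(
    scores: np.ndarray,
    binary_relevance: np.ndarray,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Reliability-diagram bins and Expected Calibration Error.

    Scores are mapped to confidences with a sigmoid; confidences are placed
    in ``n_bins`` equal-width bins on [0, 1].  Per nonempty bin the table
    reports mean confidence and empirical precision (positive fraction);
    ECE is the bin-size-weighted absolute confidence/precision gap.
    """
    scores = np.asarray(scores, dtype=np.float64)
    rel = np.asarray(binary_relevance, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("reliability_and_ece: empty input")
    if scores.shape != rel.shape:
        raise ValueError("scores and relevance differ in shape")
    if not np.isin(rel, (0.0, 1.0)).all():
        raise ValueError("relevance must be binary")
    conf = expit(scores)
    which = np.clip((conf * n_bins).astype(int), 0, n_bins - 1)
    rows = []
    ece = 0.0
    n = conf.shape[0]
    for b in range(n_bins):
        mask = which == b
        n_b = int(mask.sum())
        if n_b == 0:
            continue
        c_b = float(conf[mask].mean())
        p_b = float(rel[mask].mean())
        ece += (n_b / n) * abs(c_b - p_b)
        rows.append({"bin": b, "lo": b / n_bins, "hi": (b + 1) / n_bins,
                     "n": n_b, "confidence": c_b, "precision": p_b})
    return pd.DataFrame(rows), float(ece)


def rank_swap(ranking_full: list[str], ranking_ablated: list[str]) -> pd.DataFrame:
    """Per-candidate rank change between two rankings of the same candidates.

    delta = rank_ablated - rank_full, so positive values mark candidates the
    full model *promotes*.  Sorted by |delta| descending (ties by id).
    """
    set_f, set_a = set(ranking_full), set(ranking_ablated)
    if set_f != set_a:
        diff = sorted(set_f.symmetric_difference(set_a))
        raise ValueError(f"candidate sets differ; symmetric difference: {diff}")
    rank_f = {a: i + 1 for i, a in enumerate(ranking_full)}
    rank_a = {a: i + 1 for i, a in enumerate(ranking_ablated)}
    df = pd.DataFrame(
        {
            "candidate": sorted(set_f),
            "rank_full": [rank_f[a] for a in sorted(set_f)],
            "rank_ablated": [rank_a[a] for a in sorted(set_f)],
        }
    )
    df["delta"] = df["rank_ablated"] - df["rank_full"]
    return df.sort_values(["delta", "candidate"], key=lambda s: -s.abs() if s.name == "delta" else s,
                          ignore_index=True)
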