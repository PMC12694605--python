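"""Per-disease evaluation, macro-averaged reports with bootstrap CIs, and
model comparison (paired randomization tests, rank-swap tables).

Each disease is one query; metrics are macro-averaged unweighted across
diseases and reported with disease-level percentile-bootstrap 95% CIs
(B = 1000), in the layout Split / Metric / Mean / 95% CI / n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .kg import QuerySet
from .metrics import dcg_curves, ndcg_at_k, precision_at_k, recall_at_k
from .stats import bootstrap_ci, paired_randomization_test

#: a ranker maps a disease id to the full candidate list in predicted order
RankFn = Callable[[str], list[str]]


def per_disease_metrics(
    rank_fn: RankFn,
    queries: QuerySet,
    disease_ids: list[str],
    ks: tuple[int, ...] = (5, 10),
) -> pd.DataFrame:
    """Evaluate one ranker on the given diseases (graded gains)."""
    cand_index = {a: i for i, a in enumerate(queries.candidates)}
    rows = []
    for d in disease_ids:
        if d not in queries.gains:
            raise KeyError(f"disease {d!r} has no gains (no positives?)")
        ranked = rank_fn(d)
        if sorted(ranked) != sorted(queries.candidates):
            raise ValueError(f"ranker returned a wrong candidate set for {d!r}")
        g = queries.gains[d][np.array([cand_index[a] for a in ranked])]
        row = {"disease_id": d}
        for k in ks:
            row[f"ndcg@{k}"] = ndcg_at_k(g, k)
            row[f"recall@{k}"] = recall_at_k(g, k)
            row[f"precision@{k}"] = precision_at_k(g, k)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Macro means with CIs for one (split, ranker) pair."""

    split: str
    n_diseases: int
    B: int
    metrics: dict[str, dict[str, float]]  # name -> {mean, ci_lo, ci_hi}
    per_disease: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "n_diseases": self.n_diseases,
            "B": self.B,
            "metrics": self.metrics,
            "per_disease": self.per_disease.to_dict(orient="records"),
        }


def build_report(
    per_disease: pd.DataFrame,
    split: str,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    level: float = 0.95,
) -> EvalReport:
    if len(per_disease) == 0:
        raise ValueError(f"split {split!r} has zero evaluable diseases")
    seed = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    metric_cols = [c for c in per_disease.columns if c != "disease_id"]
    metrics = {}
    for col, ss in zip(metric_cols, seed.spawn(len(metric_cols))):
        vals = per_disease[col].to_numpy()
        mean = float(vals.mean())
        if len(vals) >= 2:
            lo, hi = bootstrap_ci(vals, B=B, level=level, seed=ss)
        else:
            lo = hi = mean
        metrics[col] = {"mean": mean, "ci_lo": lo, "ci_hi": hi}
    return EvalReport(split=split, n_diseases=len(per_disease), B=B,
                      metrics=metrics, per_disease=per_disease)


def report_markdown(reports: list[EvalReport], title: str = "Evaluation report") -> str:
    lines = [f"# {title}", "", "| Split | Metric | Mean | 95% CI | n (diseases) |",
             "|---|---|---|---|---|"]
    for r in reports:
        for name, m in r.metrics.items():
            lines.append(
                f"| {r.split} | {name} | {m['mean']:.3f} | "
                f"[{m['ci_lo']:.3f}, {m['ci_hi']:.3f}] | {r.n_diseases} |"
            )
    return "\n".join(lines) + "\n"


def write_reports(reports: list[EvalReport], out_dir: str | Path,
                  extra: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"reports": [r.to_dict() for r in reports]}
    if extra:
        payload.update(extra)
    (out / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    (out / "report.md").write_text(report_markdown(reports))


def compare_rankers(
    per_disease_a: pd.DataFrame,
    per_disease_b: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, float]:
    """Two-sided paired randomization p-value per metric (paired by disease)."""
    a = per_disease_a.set_index("disease_id").sort_index()
    b = per_disease_b.set_index("disease_id").sort_index()
    if list(a.index) != list(b.index):
        raise ValueError("compared rankers evaluated different disease sets")
    seed = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = {}
    for col, ss in zip(a.columns, seed.spawn(len(a.columns))):
        out[col] = paired_randomization_test(a[col].to_numpy(), b[col].to_numpy(),
                                             n_perm=n_perm, seed=ss)
    return out


def rankings_table(
    rank_fn: Callable[[str], list[tuple[str, float]]],
    queries: QuerySet,
    disease_ids: list[str],
    tag: str = "model",
) -> pd.DataFrame:
    """rankings.tsv payload: disease_id, rank, adjuvant_id, score, gain."""
    cand_index = {a: i for i, a in enumerate(queries.candidates)}
    rows = []
    for d in disease_ids:
        for rank, (a, s) in enumerate(rank_fn(d), start=1):
            gain = int(queries.gains[d][cand_index[a]]) if d in queries.gains else None
            rows.append({"disease_id": d, "rank": rank, "adjuvant_id": a,
                         "score": s, "gain": gain, "ranker": tag})
    return pd.DataFrame(rows)


def case_study(
    disease_id: str,
    ranked_with_scores: list[tuple[str, float]],
    queries: QuerySet,
    top_k: int = 10,
    n_bins: int = 10,
) -> dict:
    """Single-disease deep dive: top-k table, DCG/IDCG curves, calibration.

    Calibration treats sigmoid(score) as confidence and gain > 0 as the
    binary outcome, over the full candidate list.
    """
    from .metrics import reliability_and_ece

    cand_index = {a: i for i, a in enumerate(queries.candidates)}
    g = queries.gains[disease_id]
    ranked_ids = [a for a, _ in ranked_with_scores]
    scores = np.array([s for _, s in ranked_with_scores])
    g_ranked = g[np.array([cand_index[a] for a in ranked_ids])]
    bins, ece = reliability_and_ece(scores, (g_ranked > 0).astype(float), n_bins=n_bins)
    return {
        "disease_id": disease_id,
        "top_k": [
            {"rank": i + 1, "adjuvant_id": a, "score": float(s), "gain": int(gi)}
            for i, ((a, s), gi) in enumerate(zip(ranked_with_scores[:top_k], g_ranked[:top_k]))
        ],
        "ndcg@10": ndcg_at_k(g_ranked, 10),
        "precision@5": precision_at_k(g_ranked, 5),
        "curves": dcg_curves(g_ranked),
        "reliability_bins": bins,
        "ece": ece,
    }
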