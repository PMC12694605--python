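"""Comparison rankers: uniform-random and text-similarity-only.

Both receive nothing beyond the candidate list (and, for text similarity,
the raw node features): no graph edges, no mechanism cues, no learned
weights.  They contextualize the trained ranker's lift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix


@dataclass(frozen=True)
class BaselineSpec:
    kind: str  # "random" | "text_similarity"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("random", "text_similarity"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "random" and self.seed is None:
            raise ValueError("random baseline requires a seed")


def random_ranker(candidates: list[str], seed: int | np.random.SeedSequence) -> list[str]:
    """Uniform random permutation of the candidates, reproducible by seed."""
    if not candidates:
        raise ValueError("no candidates to rank")
    rng = np.random.default_rng(seed)
    return [candidates[i] for i in rng.permutation(len(candidates))]


def text_similarity_ranker(
    disease_id: str,
    candidates: list[str],
    features: FeatureMatrix,
) -> list[str]:
    """Rank candidates by cosine similarity of raw text features to the disease.

    Ties break by id ascending; a zero-norm candidate ranks below any real
    cosine (its similarity is set under -1).
    """
    rows = {nid: i for i, nid in enumerate(features.node_ids)}
    missing = [x for x in [disease_id, *candidates] if x not in rows]
    if missing:
        raise KeyError(f"no feature rows for: {missing}")
    x_d = features.X[rows[disease_id]]
    nd = np.linalg.norm(x_d)
    sims = []
    for a in candidates:
        x_a = features.X[rows[a]]
        na = np.linalg.norm(x_a)
        if na == 0.0:
            sims.append(-2.0)
        elif nd == 0.0:
            sims.append(0.0)
        else:
            sims.append(float(x_d @ x_a / (nd * na)))
    order = sorted(range(len(candidates)), key=lambda i: (-sims[i], candidates[i]))
    return [candidates[i] for i in order]
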