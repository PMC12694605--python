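"""End-to-end ranking pipeline: features → propagation → scorer.

Because both the base encoder and APPNP are linear, the raw hashed features
are propagated through the graph once (X̃ = M X with M the APPNP operator)
and the learnable affine encoder is applied afterwards — mathematically
identical to encoding first and propagating the embeddings, but it turns
every training step into dense matrix algebra with closed-form gradients.

A disease node with no edges (an unseen disease) has X̃ row equal to its own
feature row, so inductive queries need no graph surgery: scoring an isolated
disease uses exactly its encoded text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import DEFAULT_PATHWAYS, FeatureMatrix, MechanismCueMatrix, encode_nodes, read_cues
from .kg import HeteroGraph, QuerySet, query_set, read_graph, read_pairs
from .propagation import PropagationConfig, appnp
from .scorer import RankerParams, rank_candidates, score_candidates


@dataclass
class ModelConfig:
    """Hyperparameters of the full pipeline (defaults documented in docs)."""

    dim: int = 64
    d_in: int = 256
    encoder_backend: str = "hashing"
    encoder_seed: int = 0
    alpha: float = 0.1
    K: int = 10
    gamma_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    lam: float = 1e-4
    tau: float = 0.1  # surrogate temperature at the scale of typical score gaps
    mix_w: float = 0.5
    n_neg: int = 20
    lr: float = 1e-2
    epochs: int = 200
    batch_queries: int = 8
    ndcg_k: int = 10
    binary_gains: bool = False
    val_fraction: float = 0.25
    cold_start_p: float = 0.5
    pathway_vocab: list[str] = field(default_factory=lambda: list(DEFAULT_PATHWAYS))


class RankingPipeline:
    """Graph + features + cues, pre-propagated, ready to score any disease."""

    def __init__(
        self,
        graph: HeteroGraph,
        features: FeatureMatrix,
        cues: MechanismCueMatrix,
        prop_cfg: PropagationConfig,
    ):
        if features.node_ids != graph.node_ids:
            raise ValueError("feature matrix row order does not match the graph ordering")
        self.graph = graph
        self.features = features
        self.cues = cues
        self.prop_cfg = prop_cfg
        self.Xt = appnp(features.X, graph.normalized_adjacency(), prop_cfg)
        self.adjuvant_ids = graph.ids_of_type("Adjuvant")
        self._adj_rows = np.array([graph.index_of(a) for a in self.adjuvant_ids])
        if cues.adjuvant_ids != self.adjuvant_ids:
            raise ValueError("cue matrix adjuvant order does not match the graph")

    # propagated raw features, by node / for all adjuvants
    def x_node(self, node_id: str) -> np.ndarray:
        return self.Xt[self.graph.index_of(node_id)]

    @property
    def X_adjuvants(self) -> np.ndarray:
        return self.Xt[self._adj_rows]

    def embed(self, X_rows: np.ndarray, params: RankerParams) -> np.ndarray:
        return X_rows @ params.W_f + params.b_f

    def scores_for(self, disease_id: str, params: RankerParams,
                   candidate_idx: np.ndarray | None = None) -> np.ndarray:
        h_d = self.embed(self.x_node(disease_id), params)
        Xa = self.X_adjuvants if candidate_idx is None else self.X_adjuvants[candidate_idx]
        Phi = self.cues.Phi if candidate_idx is None else self.cues.Phi[candidate_idx]
        return score_candidates(h_d, self.embed(Xa, params), Phi, params)

    def rank(self, disease_id: str, params: RankerParams,
             candidates: list[str] | None = None) -> list[tuple[str, float]]:
        """Ranked (adjuvant_id, score) list, ties broken by id."""
        if candidates is None:
            ids = self.adjuvant_ids
            idx = None
        else:
            lookup = {a: i for i, a in enumerate(self.adjuvant_ids)}
            missing = [a for a in candidates if a not in lookup]
            if missing:
                raise KeyError(f"unknown adjuvant candidates: {missing}")
            ids = list(candidates)
            idx = np.array([lookup[a] for a in candidates])
        return rank_candidates(ids, self.scores_for(disease_id, params, idx))


def load_dataset(data_dir: str | Path, cfg: ModelConfig):
    """Read a fixture directory into (pipeline, queries, splits).

    Expects nodes.tsv, edges.tsv, cues.tsv, positives.tsv, classes.tsv and
    optionally splits.tsv (disease_id, split ∈ {transductive, inductive}).
    """
    data_dir = Path(data_dir)
    graph = read_graph(data_dir / "edges.tsv", data_dir / "nodes.tsv")
    feats = encode_nodes(graph, backend=cfg.encoder_backend, dim=cfg.d_in,
                         seed=cfg.encoder_seed)
    cues = read_cues(data_dir / "cues.tsv", cfg.pathway_vocab, graph.ids_of_type("Adjuvant"))
    positives = read_pairs(data_dir / "positives.tsv", ("disease_id", "adjuvant_id"))
    classes = read_pairs(data_dir / "classes.tsv", ("adjuvant_id", "class_label"))
    queries = query_set(graph, positives, classes)
    splits: dict[str, list[str]] = {"transductive": [], "inductive": []}
    split_path = data_dir / "splits.tsv"
    if split_path.exists():
        sdf = read_pairs(split_path, ("disease_id", "split"))
        for r in sdf.itertuples(index=False):
            if r.split not in splits:
                raise ValueError(f"unknown split label {r.split!r}")
            splits[r.split].append(r.disease_id)
    else:
        splits["transductive"] = queries.disease_ids
    pipeline = RankingPipeline(graph, feats, cues, PropagationConfig(cfg.alpha, cfg.K))
    return pipeline, queries, splits


# ---------------------------------------------------------------------------
# Checkpoints (versioned JSON; floats round-trip exactly via repr)
# ---------------------------------------------------------------------------

CHECKPOINT_FORMAT = "adjurank-checkpoint-v1"


def save_checkpoint(path: str | Path, params: RankerParams, cfg: ModelConfig,
                    history: dict | None = None) -> None:
    payload = {
        "format": CHECKPOINT_FORMAT,
        "config": {**asdict(cfg), "gamma_grid": list(cfg.gamma_grid)},
        "gamma": params.gamma,
        "lam": params.lam,
        "weights": {k: v.tolist() for k, v in params.trainable().items()},
        "history": history or {},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_checkpoint(path: str | Path) -> tuple[RankerParams, ModelConfig, dict]:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"{path}: not a {CHECKPOINT_FORMAT} file")
    raw_cfg = dict(obj["config"])
    raw_cfg["gamma_grid"] = tuple(raw_cfg["gamma_grid"])
    cfg = ModelConfig(**raw_cfg)
    w = {k: np.asarray(v, dtype=np.float64) for k, v in obj["weights"].items()}
    params = RankerParams(W_f=w["W_f"], b_f=w["b_f"], W=w["W"], Wm=w["Wm"],
                          gamma=float(obj["gamma"]), lam=float(obj["lam"]))
    return params, cfg, obj.get("history", {})
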