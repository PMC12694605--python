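"""Node feature initialization and mechanism-cue vectors.

Two text-encoder backends share one interface:

* ``hashing`` (default, offline): signed feature hashing of word uni/bigrams
  into a fixed ``dim``, L2-normalized per row.  Deterministic given
  (text, dim, seed) — the hash is keyed BLAKE2b, so it is stable across
  processes and platforms, unlike Python's builtin ``hash``.
* ``pretrained`` : a biomedical sentence encoder (e.g. a SapBERT-style model
  via ``sentence-transformers``).  The weights are external; if the package
  is not installed the backend raises immediately rather than silently
  substituting the hashing encoder.

Mechanism cues record which innate-immune pathway(s) an adjuvant engages
(e.g. CpG oligodeoxynucleotides → TLR9 agonism, MPLA → TLR4) as a multi-hot
binary matrix over a fixed pathway vocabulary.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kg import HeteroGraph, _read_tsv

#: Default pathway vocabulary: a small curated list of innate-immune pathway
#: tokens.  Editable via run config; order defines the cue-matrix columns.
DEFAULT_PATHWAYS = ["TLR9", "TLR4", "TLR7", "TLR3", "STING", "NLRP3", "MINCLE", "ALUM"]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class FeatureMatrix:
    """One row of initial features per node, in the graph's stable order."""

    X: np.ndarray  # |V| x D_in
    encoder_tag: str
    node_ids: list[str]

    def row(self, node_id: str) -> np.ndarray:
        return self.X[self.node_ids.index(node_id)]


def _tokens(text: str, ngrams: int = 1) -> list[str]:
    """Word n-gram tokens.  The default is unigrams: biomedical entity names
    share vocabulary heavily, and unigram bags keep that shared signal
    dominant over per-entity n-gram signatures."""
    words = _TOKEN_RE.findall(text.lower())
    out = list(words)
    for n in range(2, ngrams + 1):
        out += ["_".join(words[i:i + n]) for i in range(len(words) - n + 1)]
    return out


def hash_text(text: str, dim: int, seed: int) -> np.ndarray:
    """Signed feature hashing of one text into a dense L2-normalized vector."""
    v = np.zeros(dim, dtype=np.float64)
    key = int(seed).to_bytes(8, "little", signed=False)
    for tok in _tokens(text):
        h = int.from_bytes(
            hashlib.blake2b(tok.encode(), key=key, digest_size=8).digest(), "little"
        )
        sign = 1.0 if h & 1 else -1.0
        v[(h >> 1) % dim] += sign
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def encode_nodes(
    g: HeteroGraph,
    backend: str = "hashing",
    dim: int = 256,
    seed: int = 0,
    model_name: str = "cambridgeltl/SapBERT-from-PubMedBERT-fulltext",
) -> FeatureMatrix:
    """Encode every node's text into an initial feature row x_v.

    A pure function of (node texts, backend config, seed); two runs with the
    same inputs produce bitwise-equal matrices.
    """
    texts = [n.text for n in g.nodes]
    if backend == "hashing":
        X = np.stack([hash_text(t, dim, seed) for t in texts])
        tag = f"hashing(dim={dim},seed={seed})"
    elif backend == "pretrained":
        try:
            from sentence_transformers import SentenceTransformer  # type: ignore
        except ImportError as exc:
            raise ImportError(
                "the 'pretrained' encoder backend requires the sentence-transformers "
                "package and a model download; install it or fall back explicitly to "
                "backend='hashing' (the offline default)"
            ) from exc
        model = SentenceTransformer(model_name)
        X = np.asarray(model.encode(texts), dtype=np.float64)
        tag = f"pretrained({model_name})"
    else:
        raise ValueError(f"unknown encoder backend {backend!r}")
    if not np.isfinite(X).all():
        raise ValueError("encoder produced non-finite features")
    return FeatureMatrix(X=X, encoder_tag=tag, node_ids=g.node_ids)


# ---------------------------------------------------------------------------
# Mechanism cues
# ---------------------------------------------------------------------------

@dataclass
class MechanismCueMatrix:
    """Adjuvant × pathway multi-hot matrix Φ.

    Rows follow ``adjuvant_ids`` (the stable adjuvant order); columns follow
    ``pathway_vocab``.  All-zero rows are legal — an adjuvant with unknown
    mechanism simply contributes no prior signal.
    """

    Phi: np.ndarray  # |Adjuvant| x P, entries in {0, 1}
    pathway_vocab: list[str]
    adjuvant_ids: list[str]

    def row(self, adjuvant_id: str) -> np.ndarray:
        return self.Phi[self.adjuvant_ids.index(adjuvant_id)]


def build_cues(
    cue_table: pd.DataFrame,
    vocab: list[str],
    adjuvant_ids: list[str],
) -> MechanismCueMatrix:
    """Build Φ from a cue table with columns (adjuvant_id, pathway_token).

    Duplicate rows are idempotent; tokens outside ``vocab`` and adjuvants
    outside ``adjuvant_ids`` are errors listing the offenders.
    """
    col = {p: j for j, p in enumerate(vocab)}
    row = {a: i for i, a in enumerate(adjuvant_ids)}
    unknown_tok = sorted(set(cue_table["pathway_token"]) - set(col))
    if unknown_tok:
        raise ValueError(f"cue table uses pathway tokens outside the vocab: {unknown_tok}")
    unknown_adj = sorted(set(cue_table["adjuvant_id"]) - set(row))
    if unknown_adj:
        raise ValueError(f"cue table references unknown adjuvants: {unknown_adj}")
    Phi = np.zeros((len(adjuvant_ids), len(vocab)), dtype=np.float64)
    for r in cue_table.itertuples(index=False):
        Phi[row[r.adjuvant_id], col[r.pathway_token]] = 1.0
    return MechanismCueMatrix(Phi=Phi, pathway_vocab=list(vocab), adjuvant_ids=list(adjuvant_ids))


def read_cues(path: str | Path, vocab: list[str], adjuvant_ids: list[str]) -> MechanismCueMatrix:
    return build_cues(_read_tsv(path, ("adjuvant_id", "pathway_token")), vocab, adjuvant_ids)
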