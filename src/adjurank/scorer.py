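"""Disease-adjuvant compatibility scoring.

The score combines a bilinear interaction between propagated embeddings with
an explicit mechanism-matching prior:

    s(d, a) = h_d' W h_a  +  gamma * m(d, a)
    m(d, a) = sigmoid( (Wm h_d)' phi(a) )

Wm projects the disease embedding into a "mechanism-demand" space over the
pathway vocabulary; phi(a) is the adjuvant's multi-hot cue vector.  The
sigmoid is applied to the *scalar* alignment so m is always in (0, 1) — an
adjuvant with no known cues contributes the neutral value 0.5.  gamma >= 0
is a hyperparameter tuned on validation NDCG@10, not a trained weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass
class RankerParams:
    """All learnable weights plus the two fixed hyperparameters.

    W_f (D_in x D) and b_f (D): affine base encoder.
    W (D x D): bilinear interaction (full, unconstrained).
    Wm (P x D): mechanism projection.
    gamma >= 0: prior weight; lam >= 0: L2 coefficient.
    """

    W_f: np.ndarray
    b_f: np.ndarray
    W: np.ndarray
    Wm: np.ndarray
    gamma: float = 1.0
    lam: float = 1e-4

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        for name in ("W_f", "b_f", "W", "Wm"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite entries in {name}")

    @property
    def dim(self) -> int:
        return self.W.shape[0]

    def trainable(self) -> dict[str, np.ndarray]:
        return {"W_f": self.W_f, "b_f": self.b_f, "W": self.W, "Wm": self.Wm}

    def l2_sq(self) -> float:
        """Squared L2 norm of the penalized weights (bias excluded)."""
        return float(
            np.sum(self.W_f**2) + np.sum(self.W**2) + np.sum(self.Wm**2)
        )

    @staticmethod
    def init(d_in: int, dim: int, n_pathways: int, rng: np.random.Generator,
             gamma: float = 1.0, lam: float = 1e-4) -> "RankerParams":
        scale = 1.0 / np.sqrt(dim)
        return RankerParams(
            W_f=rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, dim)),
            b_f=np.zeros(dim),
            W=rng.normal(0.0, scale, size=(dim, dim)),
            Wm=rng.normal(0.0, scale, size=(n_pathways, dim)),
            gamma=gamma,
            lam=lam,
        )


def mechanism_match(h_d: np.ndarray, phi_a: np.ndarray, Wm: np.ndarray) -> float:
    """m(d,a) = sigmoid((Wm h_d)' phi(a)), a scalar in (0, 1)."""
    h_d, phi_a = np.asarray(h_d), np.asarray(phi_a)
    if Wm.shape[1] != h_d.shape[0] or Wm.shape[0] != phi_a.shape[0]:
        raise ValueError(
            f"shape mismatch: Wm {Wm.shape}, h_d {h_d.shape}, phi {phi_a.shape}"
        )
    return float(expit((Wm @ h_d) @ phi_a))


def score(h_d: np.ndarray, h_a: np.ndarray, phi_a: np.ndarray, params: RankerParams) -> float:
    """s(d,a) = h_d' W h_a + gamma * m(d,a)."""
    return float(h_d @ params.W @ h_a) + params.gamma * mechanism_match(h_d, phi_a, params.Wm)


def score_candidates(
    h_d: np.ndarray,
    H_a: np.ndarray,
    Phi: np.ndarray,
    params: RankerParams,
) -> np.ndarray:
    """Vectorized score over n candidates (rows of H_a and Phi)."""
    bilinear = (h_d @ params.W) @ H_a.T
    m = expit(Phi @ (params.Wm @ h_d))
    return bilinear + params.gamma * m


def order_by_score(candidate_ids: list[str], scores: np.ndarray) -> list[int]:
    """Indices sorted by score descending, ties broken by candidate id ascending."""
    return sorted(range(len(candidate_ids)), key=lambda i: (-scores[i], candidate_ids[i]))


def rank_candidates(
    candidate_ids: list[str],
    scores: np.ndarray,
) -> list[tuple[str, float]]:
    """Deterministic descending ranking of (id, score) pairs."""
    if len(candidate_ids) != len(scores):
        raise ValueError("candidate ids and scores differ in length")
    return [(candidate_ids[i], float(scores[i])) for i in order_by_score(candidate_ids, scores)]
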