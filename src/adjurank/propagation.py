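"""Base encoder and personalized-PageRank (APPNP) smoothing of node embeddings.

The base encoder is an affine map z_v = x_v W_f + b_f.  APPNP then smooths
embeddings over the graph with a lazy random walk plus teleport:

    H(0) = Z,    H(k) = (1 - alpha) Â H(k-1) + alpha Z,    k = 1..K

where Â is the row-stochastic self-looped adjacency.  As K → ∞ this converges
to alpha (I - (1 - alpha) Â)⁻¹ Z, the personalized-PageRank diffusion of Z.
Because the recurrence is linear, propagating the raw features once and
applying the encoder afterwards is exactly equivalent to encoding first and
propagating the embeddings (Â is row-stochastic so the bias is a fixed point);
training exploits this to keep gradients closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class PropagationConfig:
    """Teleport probability alpha ∈ (0, 1) and step count K ≥ 0.

    Defaults alpha=0.1, K=10 are the standard APPNP settings.
    """

    alpha: float = 0.1
    K: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")


def base_encode(X: np.ndarray, W_f: np.ndarray, b_f: np.ndarray) -> np.ndarray:
    """Affine base encoder Z = X W_f + b_f."""
    X = np.asarray(X)
    if X.shape[1] != W_f.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match encoder input dim {W_f.shape[0]} "
            f"(W_f shape {W_f.shape})"
        )
    if b_f.shape != (W_f.shape[1],):
        raise ValueError(f"bias shape {b_f.shape} does not match output dim {W_f.shape[1]}")
    return X @ W_f + b_f


def _check_row_stochastic(A_hat, n_rows: int) -> None:
    sums = np.asarray(A_hat.sum(axis=1)).ravel()
    if sums.shape[0] != n_rows or not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("A_hat must be square row-stochastic with one row per embedding row")


def appnp(Z: np.ndarray, A_hat, cfg: PropagationConfig) -> np.ndarray:
    """Run K APPNP steps and return H = H(K).  K=0 returns Z unchanged."""
    Z = np.asarray(Z, dtype=np.float64)
    if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[0] != Z.shape[0]:
        raise ValueError(f"shape mismatch: A_hat {A_hat.shape} vs Z {Z.shape}")
    _check_row_stochastic(A_hat, Z.shape[0])
    H = Z
    for _ in range(cfg.K):
        H = (1.0 - cfg.alpha) * (A_hat @ H) + cfg.alpha * Z
    return np.asarray(H)


def appnp_operator(A_hat, cfg: PropagationConfig) -> sp.csr_matrix:
    """The linear operator M with appnp(Z) = M Z, as a sparse/dense matrix.

    M = alpha Σ_{k<K} ((1-alpha) Â)^k + ((1-alpha) Â)^K; its rows sum to one.
    Used to pre-propagate raw features once before training.
    """
    n = A_hat.shape[0]
    M = sp.identity(n, format="csr")
    B = (1.0 - cfg.alpha) * sp.csr_matrix(A_hat)
    for _ in range(cfg.K):
        M = B @ M + cfg.alpha * sp.identity(n, format="csr")
    return sp.csr_matrix(M)
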