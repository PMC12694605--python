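"""Uncertainty quantification for per-query (per-disease) IR metrics.

Two seeded, pure-function procedures:

* percentile bootstrap over diseases (resample queries with replacement,
  recompute the macro mean, take empirical percentiles);
* two-sided paired randomization (sign-flip) test on per-disease metric
  differences — exhaustive over all 2^n flips for n <= 12, Monte Carlo with
  add-one smoothing otherwise.
"""

from __future__ import annotations

import numpy as np

EXHAUSTIVE_MAX_N = 12


def bootstrap_ci(
    values: np.ndarray,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the macro mean of per-disease values."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.shape[0] < 2:
        raise ValueError("bootstrap_ci needs a 1-d sample of size >= 2")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    idx = rng.integers(0, n, size=(B, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def paired_randomization_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Two-sided p-value for mean(a - b) = 0 under random sign flips.

    The null distribution flips the sign of each paired difference
    independently.  For n <= 12 all 2^n sign patterns are enumerated and the
    exact fraction |null| >= |observed| is returned; otherwise ``n_perm``
    random flips are drawn and the add-one-smoothed fraction is returned.
    Symmetric in (a, b); identical samples give p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must have equal length: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = a - b
    obs = abs(d.mean())
    tol = 1e-12  # |null| >= |obs| decided with a float-noise guard

    if n <= EXHAUSTIVE_MAX_N:
        # all 2^n sign patterns, vectorized via the binary expansion
        patterns = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        signs = 2.0 * patterns - 1.0
        null = np.abs((signs * d).mean(axis=1))
        return float(np.mean(null >= obs - tol))

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null = np.abs((signs * d).mean(axis=1))
    hits = int(np.sum(null >= obs - tol))
    return float((hits + 1) / (n_perm + 1))
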