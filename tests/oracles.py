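"""Independent brute-force oracles, written separately from the package.

These deliberately use the most naive formulation possible (explicit loops,
dense linear solves, exhaustive enumeration) so they share no code path with
the implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_dcg(gains, k):
    total = 0.0
    for i, g in enumerate(gains[:k], start=1):
        total += g / math.log2(i + 1)
    return total


def brute_ndcg(gains, k):
    ideal = brute_dcg(sorted(gains, reverse=True), k)
    return brute_dcg(gains, k) / ideal


def brute_recall(gains, k):
    rel = sum(1 for g in gains if g > 0)
    return sum(1 for g in gains[:k] if g > 0) / rel


def brute_precision(gains, k):
    return sum(1 for g in gains[:k] if g > 0) / k


def closed_form_appnp(Z, A_hat, alpha):
    """Fixed point alpha (I - (1-alpha) A)^-1 Z via a dense solve."""
    A = np.asarray(A_hat.todense() if hasattr(A_hat, "todense") else A_hat)
    n = A.shape[0]
    return alpha * np.linalg.solve(np.eye(n) - (1 - alpha) * A, np.asarray(Z))


def exhaustive_mean_ndcg(gains, k):
    """Expected NDCG@k of a uniformly random permutation (all n! orders)."""
    vals = [brute_ndcg(list(p), k) for p in itertools.permutations(gains)]
    return sum(vals) / len(vals)


def exhaustive_sign_flip_p(diffs):
    """Two-sided exact randomization p-value over all 2^n sign patterns."""
    n = len(diffs)
    obs = abs(sum(diffs) / n)
    hits = 0
    for signs in itertools.product((-1, 1), repeat=n):
        stat = abs(sum(s * d for s, d in zip(signs, diffs)) / n)
        if stat >= obs - 1e-12:
            hits += 1
    return hits / 2**n
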