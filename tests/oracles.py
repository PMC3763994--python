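"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and libraries) they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_max_margin_2d(X: np.ndarray, y: np.ndarray) -> float:
    """Exact maximum geometric margin of a separable 2-class 2-D point set.

    In the plane, the maximum-margin separator's normal is either the
    difference of a closest cross-class point pair or the normal of a
    convex-hull edge of one class, so enumerating all point pairs and all
    same-class edges and maximizing the worst-case half-gap over those
    directions is exhaustive.  Returns the half-margin (distance from the
    separator to the closest point).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    assert len(labels) == 2 and X.shape[1] == 2
    A = X[y == labels[0]]
    B = X[y == labels[1]]

    candidates: list[np.ndarray] = [p - q for p in A for q in B]
    for G in (A, B):
        for i in range(len(G)):
            for j in range(i + 1, len(G)):
                e = G[i] - G[j]
                candidates.append(np.array([-e[1], e[0]]))

    best = -np.inf
    for w in candidates:
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            continue
        u = w / nw
        for direction in (u, -u):
            gap = (np.min(A @ direction) - np.max(B @ direction)) / 2.0
            best = max(best, gap)
    return best


def gaussian_midpoint_accuracy(delta: float, sigma: float, n: int,
                               rng: np.random.Generator,
                               n_sim: int = 100_000) -> float:
    """Monte-Carlo accuracy of the midpoint threshold between two
    equal-variance Gaussians after averaging ``n`` draws (simulation
    counterpart of the closed form, built from raw normal draws only)."""
    means = rng.standard_normal((n_sim, n)).mean(axis=1) * sigma + delta / 2.0
    correct_pos = np.mean(means > 0)
    means_neg = rng.standard_normal((n_sim, n)).mean(axis=1) * sigma - delta / 2.0
    correct_neg = np.mean(means_neg <= 0)
    return float((correct_pos + correct_neg) / 2.0)
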