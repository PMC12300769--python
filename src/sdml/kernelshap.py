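"""Kernel SHAP: model-agnostic Shapley estimation by weighted regression.

Coalitions of present/absent features are scored by replacing absent features
with values from a background set — here the k-means cluster centers of the
reference data, weighted by cluster size — and a weighted least-squares fit
under the Shapley kernel recovers the attributions. Coalitions are enumerated
exhaustively whenever the feature count permits, which makes the estimate
exact up to the background approximation; otherwise they are sampled.
The efficiency constraint (attributions summing to f(x) - E[f]) is imposed by
eliminating one attribution, so additivity holds by construction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from sklearn.cluster import KMeans


def kmeans_background(X: np.ndarray, k: int = 10, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cluster centers and size weights summarizing the reference data."""
    X = np.asarray(X, dtype=float)
    k = min(k, len(X))
    if k == len(X):
        return X, np.full(len(X), 1.0 / len(X))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    weights = np.bincount(km.labels_, minlength=k).astype(float)
    return km.cluster_centers_, weights / weights.sum()


def _coalitions(M: int, budget: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(z matrix, kernel weights) for the regression, excluding empty/full."""
    total = 2**M - 2
    if total <= budget:
        zs, ws = [], []
        for s in range(1, M):
            w = (M - 1) / (comb(M, s) * s * (M - s))
            for idx in combinations(range(M), s):
                z = np.zeros(M)
                z[list(idx)] = 1
                zs.append(z)
                ws.append(w)
        return np.array(zs), np.array(ws)
    sizes = np.arange(1, M)
    size_w = (M - 1) / (sizes * (M - sizes))
    probs = size_w / size_w.sum()
    zs = np.zeros((budget, M))
    for i in range(budget):
        s = rng.choice(sizes, p=probs)
        idx = rng.choice(M, size=s, replace=False)
        zs[i, idx] = 1
    return zs, np.ones(budget)


def kernel_shap(
    predict,
    X: np.ndarray,
    background: np.ndarray,
    background_weights: np.ndarray | None = None,
    max_samples: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """(phi matrix, base value) for arbitrary ``predict`` over rows of X."""
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, M = X.shape
    bw = (
        np.full(len(background), 1.0 / len(background))
        if background_weights is None
        else np.asarray(background_weights, dtype=float)
    )
    if max_samples is None:
        max_samples = 2 * M + 2048
    base = float(np.dot(bw, predict(background)))
    rng = np.random.default_rng(seed)
    zs, ws = _coalitions(M, max_samples, rng)

    phi = np.zeros((n, M))
    fx = predict(X)
    for r in range(n):
        x = X[r]
        # synthetic rows: coalition features from x, the rest from each center
        ey = np.zeros(len(zs))
        for bi, (center, wb) in enumerate(zip(background, bw)):
            data = np.where(zs == 1, x[None, :], center[None, :])
            ey += wb * predict(data)
        target = ey - base
        # eliminate phi_{M-1} via the efficiency constraint
        excess = float(fx[r]) - base
        A = zs[:, :-1] - zs[:, -1:]
        b = target - zs[:, -1] * excess
        sw = np.sqrt(ws)
        beta, *_ = np.linalg.lstsq(A * sw[:, None], b * sw, rcond=None)
        phi[r, :-1] = beta
        phi[r, -1] = excess - beta.sum()
    return phi, base
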