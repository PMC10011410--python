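"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the code paths of the package: eigendecomposition
of the Gram matrix instead of SVD, explicit matrix inverse instead of
Cholesky solves, and naive loops instead of vectorized updates.
"""

from __future__ import annotations

import numpy as np


def brute_mahalanobis(treatment, vehicle, variance_target: float = 0.90) -> float:
    """Direct-formula activity score: scaled uncentered PCA via the Gram
    matrix, pooled group covariances, explicit inverse quadratic form."""
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(vehicle, dtype=float)
    X = np.vstack([t, c])
    n = X.shape[0]
    Xs = X / np.sqrt((X**2).sum(axis=0) / (n - 1))
    eigval, eigvec = np.linalg.eigh(Xs.T @ Xs)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    cum = np.cumsum(eigval / eigval.sum())
    q = int(np.flatnonzero(cum >= variance_target - 1e-12)[0]) + 1
    scores = Xs @ eigvec[:, :q]
    s_t, s_c = scores[: len(t)], scores[len(t):]

    def cov(a):
        d = a - a.mean(axis=0)
        return d.T @ d / (len(a) - 1)

    sigma = (len(t) * cov(s_t) + len(c) * cov(s_c)) / n
    diff = s_t.mean(axis=0) - s_c.mean(axis=0)
    return float(np.sqrt(diff @ np.linalg.inv(sigma) @ diff))


def brute_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def brute_greedy_reduce(X: np.ndarray, names: list[str], threshold: float) -> list[str]:
    """Naive re-derivation of the greedy worst-pair elimination."""
    alive = list(range(X.shape[1]))
    while True:
        worst_pair, worst_r = None, threshold
        for ii, i in enumerate(alive):
            for j in alive[ii + 1:]:
                r = abs(brute_pearson(X[:, i], X[:, j]))
                if r > worst_r:
                    worst_pair, worst_r = (i, j), r
        if worst_pair is None:
            return [names[i] for i in alive]
        i, j = worst_pair
        mean_i = np.mean([abs(brute_pearson(X[:, i], X[:, k])) for k in alive if k != i])
        mean_j = np.mean([abs(brute_pearson(X[:, j], X[:, k])) for k in alive if k != j])
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = i if names[i] > names[j] else j
        alive.remove(drop)


def brute_uncentered_pca_coords(X: np.ndarray) -> np.ndarray:
    """Coordinates from eigendecomposition of the uncentered scaled cross-product."""
    n = X.shape[0]
    Xs = X / np.sqrt((X**2).sum(axis=0) / (n - 1))
    eigval, eigvec = np.linalg.eigh(Xs.T @ Xs)
    order = np.argsort(eigval)[::-1]
    return Xs @ eigvec[:, order]
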