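"""Lloyd's K-means over patch vectors — the segmentation stage of S-DL.

The objective H is the sum over clusters of squared Euclidean distances
between each member and its center; one Lloyd iteration assigns every
point to its nearest center (ties to the lowest center index) and then
moves each center to the mean of its members, so H is non-increasing.
A cluster left empty by an assignment is re-seeded with the point
farthest from its current center.

Authored here rather than delegated to :class:`sklearn.cluster.KMeans`
because the surrounding pipeline relies on contracts sklearn does not
expose: the exact lowest-index tie-break, the recorded per-iteration
objective trace, and the deterministic single-restart seeded
initialization.  sklearn serves as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .patches import PatchSet

__all__ = ["LloydKMeans", "kmeans_fit", "kmeans_assign"]


def _as_points(data) -> np.ndarray:
    """Coerce a PatchSet (columns = patches) or matrix (rows = points)."""
    if isinstance(data, PatchSet):
        return np.ascontiguousarray(data.data.T)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D data matrix, got shape {arr.shape}")
    return arr


class LloydKMeans(ClusterMixin, BaseEstimator):
    """Seeded, deterministic Lloyd K-means.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K (1 <= K <= n_points).
    init : {"random", "farthest"}
        "random" draws K distinct data points (seeded); "farthest" is a
        greedy spread-out start: the point farthest from the data mean,
        then repeatedly the point maximizing the distance to the centers
        chosen so far.
    n_init : int
        Number of independent seeded restarts; the fit with the lowest
        final objective H is kept.
    max_iter : int
        Maximum Lloyd iterations.
    tol : float
        Convergence threshold on the relative decrease of the objective.
    random_state : int
        Seed; mandatory determinism — two fits with equal seeds are
        bit-identical.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    labels_ : ndarray of int
    inertia_ : float
        Final objective H (sum of squared distances to assigned centers).
    inertia_history_ : list of float
        H after each Lloyd iteration; non-increasing.
    n_iter_ : int
    """

    def __init__(
        self,
        n_clusters: int = 8,
        *,
        init: str = "random",
        n_init: int = 1,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        if self.init == "random":
            idx = rng.choice(n, size=self.n_clusters, replace=False)
            return X[np.sort(idx)].copy()
        if self.init == "farthest":
            chosen = [int(np.argmax(((X - X.mean(axis=0)) ** 2).sum(axis=1)))]
            min_d2 = ((X - X[chosen[0]]) ** 2).sum(axis=1)
            while len(chosen) < self.n_clusters:
                nxt = int(np.argmax(min_d2))
                chosen.append(nxt)
                min_d2 = np.minimum(min_d2, ((X - X[nxt]) ** 2).sum(axis=1))
            return X[chosen].copy()
        raise ValueError(f"unknown init '{self.init}'")

    def fit(self, X, y=None):
        X = _as_points(X)
        n = X.shape[0]
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n_points={n}")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        best = None
        for restart in range(self.n_init):
            state = self._run(X, seed=self.random_state + restart)
            if best is None or state[2][-1] < best[2][-1]:
                best = state
        self.cluster_centers_, self.labels_, history, self.n_iter_ = best
        self.inertia_ = history[-1]
        self.inertia_history_ = history
        return self

    def _run(self, X, seed: int):
        n = X.shape[0]
        centers = self._init_centers(X, seed)
        history: list[float] = []
        prev_h = np.inf
        labels = np.zeros(n, dtype=int)
        for iteration in range(1, self.max_iter + 1):
            d2 = cdist(X, centers, "sqeuclidean")
            labels = np.argmin(d2, axis=1)  # ties -> lowest index
            # Re-seed empty clusters with the point farthest from its center;
            # loop because moving a point can itself empty a singleton cluster.
            while True:
                counts = np.bincount(labels, minlength=self.n_clusters)
                empty = np.flatnonzero(counts == 0)
                if empty.size == 0:
                    break
                k = int(empty[0])
                # Only steal from clusters with more than one member.
                movable = counts[labels] > 1
                own_d2 = np.where(movable, d2[np.arange(n), labels], -np.inf)
                worst = int(np.argmax(own_d2))
                labels[worst] = k
                d2[worst, k] = 0.0
            for k in range(self.n_clusters):
                centers[k] = X[labels == k].mean(axis=0)
            h = float(((X - centers[labels]) ** 2).sum())
            history.append(h)
            if np.isfinite(prev_h) and prev_h - h <= self.tol * max(
                prev_h, np.finfo(float).tiny
            ):
                break
            prev_h = h
        return centers, labels, history, iteration

    def predict(self, X) -> np.ndarray:
        X = _as_points(X)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"data has {X.shape[1]} features, centers have "
                f"{self.cluster_centers_.shape[1]}"
            )
        return np.argmin(cdist(X, self.cluster_centers_, "sqeuclidean"), axis=1)


def kmeans_fit(
    data,
    n_clusters: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: str = "random",
    n_init: int = 1,
) -> LloydKMeans:
    """Fit K-means on a PatchSet (columns = patches) or point matrix."""
    return LloydKMeans(
        n_clusters, init=init, n_init=n_init, max_iter=max_iter, tol=tol,
        random_state=seed,
    ).fit(data)


def kmeans_assign(model: LloydKMeans, data) -> np.ndarray:
    """Nearest-center labels for new data, ties to the lowest center index."""
    return model.predict(data)
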