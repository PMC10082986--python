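"""Davies–Bouldin cluster-validity index and the subset-fitness surface.

The DB index scores how clearly the class labels partition a point set:
lower values mean tighter classes that sit farther apart.  It is the
fitness the genetic search minimizes, computed on the low-dimensional
embedding of each candidate gene subset.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .manifold import GraphDisconnectedError, classical_mds, isomap

log = logging.getLogger(__name__)


def db_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies–Bouldin index (q=1, Euclidean centroids and scatters).

    With centroid μ_i and scatter S_i = mean distance of class-i points to
    μ_i, and M_ij = ‖μ_i − μ_j‖₂:

        DB = (1/C) Σ_i max_{j≠i} (S_i + S_j) / M_ij

    Returns +inf when two class centroids coincide while their scatters are
    nonzero (the subset offers no separation at all); a 0/0 ratio between
    coincident singletons counts as 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("db_index requires at least 2 classes")
    centroids = np.stack([points[labels == c].mean(axis=0) for c in classes])
    scatters = np.array(
        [
            np.linalg.norm(points[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(classes)
        ]
    )
    M = squareform(pdist(centroids))
    C = classes.size
    worst = np.empty(C)
    for i in range(C):
        ratios = np.empty(C)
        for j in range(C):
            if j == i:
                ratios[j] = -np.inf
                continue
            s = scatters[i] + scatters[j]
            if M[i, j] == 0.0:
                ratios[j] = np.inf if s > 0 else 0.0
            else:
                ratios[j] = s / M[i, j]
        worst[i] = ratios.max()
    return float(worst.mean())


class SubsetFitness:
    """Memoized DB-of-embedding fitness for gene subsets.

    ``mode``: ``isomap`` embeds the subset's columns via k-NN geodesic MDS;
    ``mds`` applies classical MDS to the Euclidean distances (the linear
    ablation); ``none`` scores the raw subset columns.  A disconnected
    neighbourhood graph maps to +inf so the minimizing search simply avoids
    such subsets.  Results are cached per sorted index tuple.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        k: int | None,
        d: int | None,
        mode: str = "isomap",
    ):
        if mode not in ("isomap", "mds", "none"):
            raise ValueError(f"unknown embedding mode {mode!r}")
        if mode == "isomap" and k is None:
            raise ValueError("isomap mode requires k")
        if mode in ("isomap", "mds") and d is None:
            raise ValueError(f"{mode} mode requires d")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.k = k
        self.d = d
        self.mode = mode
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, subset) -> float:
        key = tuple(sorted(int(i) for i in subset))
        if key in self._cache:
            return self._cache[key]
        Xs = self.X[:, key]
        if self.mode == "isomap":
            try:
                coords = isomap(Xs, self.k, self.d).coords
            except GraphDisconnectedError:
                self._cache[key] = np.inf
                return np.inf
        elif self.mode == "mds":
            D = squareform(pdist(Xs))
            coords = classical_mds(D, self.d).coords
        else:
            coords = Xs
        value = db_index(coords, self.y)
        self._cache[key] = value
        return value

    @property
    def cache_size(self) -> int:
        return len(self._cache)
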