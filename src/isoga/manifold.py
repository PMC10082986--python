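"""Isomap from first principles: k-NN graph, geodesic distances, classical
MDS, maximum-likelihood intrinsic-dimension estimation, and DB-driven
selection of the neighbourhood size k.

The embedding pipeline follows the classic construction: connect each point
to its k nearest Euclidean neighbours, symmetrize the relation by union (an
edge survives if either endpoint lists the other), estimate geodesic
distances as all-pairs shortest paths (Floyd–Warshall), and embed by
classical multidimensional scaling of the geodesic matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components, floyd_warshall
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)


class GraphDisconnectedError(RuntimeError):
    """The k-NN graph splits into several components.

    Carries the component sizes so callers can decide whether to map the
    condition to a worst-case fitness (GA) or skip the parameter (k grid).
    """

    def __init__(self, component_sizes: list[int]):
        self.component_sizes = component_sizes
        super().__init__(
            f"neighbourhood graph is disconnected (component sizes {component_sizes})"
        )


@dataclass
class NeighborhoodGraph:
    """Symmetric weighted adjacency: Euclidean edge weights, +inf = absent."""

    weights: np.ndarray
    k: int

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class GeodesicMatrix:
    distances: np.ndarray
    connected: bool


@dataclass
class Embedding:
    """n x d coordinates ordered by descending eigenvalue, centered."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    d: int


def build_knn_graph(X: np.ndarray, k: int) -> NeighborhoodGraph:
    """Directed k-NN relation, symmetrized by union.

    Distance ties are broken by lower point index (stable argsort); each
    point's self-distance is excluded.  Duplicate points yield zero-weight
    edges but never self-loops.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} outside [1, n-1] for n={n}")
    dist = squareform(pdist(X))
    ranked = dist.copy()
    np.fill_diagonal(ranked, -1.0)  # self always ranks first, then dropped
    order = np.argsort(ranked, axis=1, kind="stable")
    neighbors = order[:, 1 : k + 1]
    adj = np.full((n, n), np.inf)
    rows = np.repeat(np.arange(n), k)
    adj[rows, neighbors.ravel()] = dist[rows, neighbors.ravel()]
    adj = np.minimum(adj, adj.T)  # union symmetrization
    np.fill_diagonal(adj, 0.0)
    return NeighborhoodGraph(weights=adj, k=k)


def shortest_paths(graph: NeighborhoodGraph) -> GeodesicMatrix:
    """All-pairs shortest-path (geodesic) distances via Floyd–Warshall."""
    D = floyd_warshall(graph.weights, directed=False)
    connected = bool(np.isfinite(D).all())
    return GeodesicMatrix(distances=D, connected=connected)


def _component_sizes(weights: np.ndarray) -> list[int]:
    finite = np.isfinite(weights)
    n_comp, assign = connected_components(finite, directed=False)
    return sorted(np.bincount(assign).tolist(), reverse=True)


def classical_mds(D: np.ndarray, d: int) -> Embedding:
    """Spectral embedding of a distance matrix.

    Double-centers the squared distances, K = -1/2 J D² J with
    J = I - (1/n) 1 1ᵀ, takes the top-d eigenpairs of K and scales the
    eigenvectors by the square roots of their (nonnegative-clamped)
    eigenvalues.  Sign convention: the largest-magnitude entry of each
    eigenvector is made positive, so embeddings are reproducible.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"target dimension d={d} outside [1, n-1] for n={n}")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries")
    J = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * J @ (D * D) @ J
    K = (K + K.T) / 2.0
    evals, evecs = eigh(K, subset_by_index=(n - d, n - 1))
    # eigh returns ascending; flip to descending eigenvalue order
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    n_pos = int((evals > 0).sum())
    if n_pos < d:
        log.warning(
            "only %d positive eigenvalues for requested d=%d; padding with zeros",
            n_pos, d,
        )
    clamped = np.clip(evals, 0.0, None)
    for j in range(d):
        pivot = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[pivot, j] < 0:
            evecs[:, j] = -evecs[:, j]
    coords = evecs * np.sqrt(clamped)
    return Embedding(coords=coords, eigenvalues=evals.copy(), d=d)


def isomap(X: np.ndarray, k: int, d: int) -> Embedding:
    """k-NN graph → geodesic distances → classical MDS.

    Raises :class:`GraphDisconnectedError` when the graph has several
    components rather than silently embedding the largest one.
    """
    graph = build_knn_graph(X, k)
    geo = shortest_paths(graph)
    if not geo.connected:
        raise GraphDisconnectedError(_component_sizes(graph.weights))
    return classical_mds(geo.distances, d)


def estimate_intrinsic_dim(
    X: np.ndarray,
    neighbor_range: tuple[int, int] = (5, 12),
    max_dim: int | None = None,
) -> int:
    """Maximum-likelihood intrinsic dimension (Levina–Bickel form).

    For each point x and neighbourhood size k, the local estimate is
    ``m̂_k(x) = [(1/(k-1)) Σ_{j<k} ln(T_k(x)/T_j(x))]⁻¹`` with T_j the
    distance to the j-th nearest neighbour.  Local estimates are combined
    over points by averaging the inverses, then averaged over k in
    ``neighbor_range``, rounded to the nearest integer and floored at 1.
    ``max_dim`` optionally caps the result (e.g. at min(n-2, m-1) when the
    embedding feeds an m-gene subset search).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k1, k2 = neighbor_range
    k2 = min(k2, n - 2)
    k1 = min(k1, k2)
    if k1 < 3:
        raise ValueError("neighbor_range must start at k >= 3")
    dist = squareform(pdist(X))
    np.fill_diagonal(dist, np.inf)
    T = np.sort(dist, axis=1)[:, :k2]  # T[:, j-1] = distance to j-th neighbour
    if np.all(T[:, 0] == 0):
        raise ValueError("all points are duplicates; dimension undefined")
    estimates = []
    for k in range(k1, k2 + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.log(T[:, k - 1 : k] / T[:, : k - 1])
        valid = np.isfinite(ratios)
        if not valid.all():
            log.warning("duplicate points: skipping %d degenerate log terms",
                        int((~valid).sum()))
        sums = np.where(valid, ratios, 0.0).sum(axis=1)
        counts = valid.sum(axis=1)
        ok = (counts > 0) & (sums > 0)
        inv_m = sums[ok] / counts[ok]  # 1 / m̂_k(x)
        if inv_m.size == 0:
            continue
        estimates.append(1.0 / inv_m.mean())
    if not estimates:
        raise ValueError("no usable neighbourhood produced a dimension estimate")
    d = max(1, int(round(float(np.mean(estimates)))))
    if max_dim is not None:
        d = min(d, max_dim)
    return d


def tune_k(
    X: np.ndarray,
    y: np.ndarray,
    d: int,
    k_range: tuple[int, int] = (5, 20),
) -> int:
    """Grid-search the neighbourhood size minimizing the DB index.

    k values whose graph is disconnected are skipped; ties go to the
    smaller k.  The range is clipped to [1, n-1].
    """
    from .cluster_validity import db_index

    n = X.shape[0]
    lo = max(1, k_range[0])
    hi = min(k_range[1], n - 1)
    if lo > hi:
        raise ValueError(f"k_range {k_range} empty after clipping to n-1={n - 1}")
    best_k, best_db = None, np.inf
    for k in range(lo, hi + 1):
        try:
            emb = isomap(X, k, d)
        except GraphDisconnectedError:
            log.debug("k=%d skipped: disconnected graph", k)
            continue
        db = db_index(emb.coords, y)
        if db < best_db:
            best_k, best_db = k, db
    if best_k is None:
        raise ValueError(
            f"every k in [{lo}, {hi}] gives a disconnected graph; widen k_range"
        )
    return best_k
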