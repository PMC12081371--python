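"""Neighbor-graph construction over a point cloud.

A cloud is viewed as an undirected graph: every point is a node and
edges encode spatial proximity.  Three constructions are supported:

* ``knn``       — each point is linked to its k nearest neighbors
                  (directed lists; ties broken by ascending index),
* ``threshold`` — edge {i, j} present iff dist(i, j) < d_thresh (strict),
* ``radius``    — neighborhood of i is every j != i with dist <= r
                  (boundary included).

The self point is excluded from every neighbor list; edge convolution
re-adds it explicitly as a self-loop during aggregation.

``local_density`` is the mean distance from a point to its k nearest
neighbors.  Note the convention: *larger* values mean a locally sparser
cloud, despite the name — the statistic is kept as conventionally
written and is exposed as a diagnostic and as the optional adaptive
per-point radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "NeighborGraph",
    "knn_neighbors",
    "threshold_edges",
    "radius_neighborhood",
    "adaptive_radius_neighborhood",
    "adjacency_matrix",
    "local_density",
]


@dataclass
class NeighborGraph:
    """Per-point neighbor index lists plus the construction that made them."""

    neighbor_lists: list
    n_nodes: int
    construction: str
    param: float

    def __post_init__(self) -> None:
        for i, nbrs in enumerate(self.neighbor_lists):
            nbrs = np.asarray(nbrs, dtype=int)
            if nbrs.size and (nbrs.min() < 0 or nbrs.max() >= self.n_nodes):
                raise ValueError("neighbor index out of range")
            if np.any(nbrs == i):
                raise ValueError("self-loops are not allowed in neighbor lists")
            self.neighbor_lists[i] = nbrs

    def undirected_edges(self) -> set:
        """Set of unordered edge pairs implied by the neighbor lists."""
        edges = set()
        for i, nbrs in enumerate(self.neighbor_lists):
            for j in nbrs:
                edges.add((min(i, int(j)), max(i, int(j))))
        return edges


def _pairwise(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (N, 3) array")
    return cdist(coords, coords)


def knn_neighbors(coords: np.ndarray, k: int) -> NeighborGraph:
    """k-nearest-neighbor lists, sorted by (distance, index), self excluded."""
    D = _pairwise(coords)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for a kNN graph")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    np.fill_diagonal(D, np.inf)
    # stable sort on distances == (distance, index) lexicographic tie-break
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    lists = [order[i] for i in range(n)]
    return NeighborGraph(lists, n, "knn", float(k))


def threshold_edges(coords: np.ndarray, d_thresh: float) -> NeighborGraph:
    """Symmetric edges between all pairs strictly closer than d_thresh."""
    if d_thresh <= 0:
        raise ValueError("d_thresh must be positive")
    D = _pairwise(coords)
    n = D.shape[0]
    mask = D < d_thresh
    np.fill_diagonal(mask, False)
    lists = [np.flatnonzero(mask[i]) for i in range(n)]
    return NeighborGraph(lists, n, "threshold", float(d_thresh))


def radius_neighborhood(coords: np.ndarray, r: float) -> NeighborGraph:
    """All points within distance r (inclusive) of each point, self excluded."""
    if r < 0:
        raise ValueError("r must be >= 0")
    D = _pairwise(coords)
    n = D.shape[0]
    mask = D <= r
    np.fill_diagonal(mask, False)
    lists = [np.flatnonzero(mask[i]) for i in range(n)]
    return NeighborGraph(lists, n, "radius", float(r))


def adjacency_matrix(graph: NeighborGraph) -> np.ndarray:
    """Binary adjacency matrix: symmetric, zero diagonal.

    Directed kNN lists are symmetrized (an edge exists when either endpoint
    lists the other).
    """
    n = graph.n_nodes
    A = np.zeros((n, n), dtype=np.int8)
    for i, nbrs in enumerate(graph.neighbor_lists):
        A[i, nbrs] = 1
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0)
    return A


def adaptive_radius_neighborhood(coords: np.ndarray, k: int) -> NeighborGraph:
    """Radius neighborhoods with per-point radii r_i = local_density(i).

    Experimental: each point's radius is its mean distance to its k nearest
    neighbors, so sparse regions reach farther.  The relation is directed
    (j within i's radius does not imply the converse).
    """
    coords = np.asarray(coords, dtype=float)
    radii = local_density(coords, k)
    D = _pairwise(coords)
    n = D.shape[0]
    np.fill_diagonal(D, np.inf)
    lists = [np.flatnonzero(D[i] <= radii[i]) for i in range(n)]
    return NeighborGraph(lists, n, "radius", float("nan"))


def local_density(coords: np.ndarray, k: int) -> np.ndarray:
    """Mean Euclidean distance from each point to its k nearest neighbors."""
    coords = np.asarray(coords, dtype=float)
    graph = knn_neighbors(coords, k)
    out = np.empty(graph.n_nodes)
    for i, nbrs in enumerate(graph.neighbor_lists):
        out[i] = np.linalg.norm(coords[nbrs] - coords[i], axis=1).mean()
    return out
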