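"""Edge convolution over a neighbor graph.

The update for node i is

    h_i = sigma( W . mean_{j in N(i) u {i}} x_j )

i.e. neighbor features plus an explicit self-loop are averaged (the
normalizer is |N(i)| + 1), linearly mixed by a weight matrix shared
across nodes, and passed through Leaky ReLU.  Aggregation is linear in
the features, so it is implemented once as a sparse row-stochastic
matrix; stacking L layers grows each node's receptive field to its
L-hop graph neighborhood, which :func:`receptive_field` computes
directly for diagnostics.

An optional *dynamic* mode rebuilds the kNN graph from each layer's
output features (feature-space neighborhoods as in DGCNN); the default
keeps the spatial graph fixed, matching the neighborhood definitions
being distances between 3D points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import NeighborGraph, knn_neighbors

__all__ = [
    "EdgeConvParams",
    "leaky_relu",
    "leaky_relu_grad",
    "aggregation_matrix",
    "edgeconv_layer",
    "stack_edgeconv",
    "receptive_field",
]

DEFAULT_LEAKY_SLOPE = 0.2


def leaky_relu(x, slope: float = DEFAULT_LEAKY_SLOPE):
    """Elementwise x if x > 0 else slope * x.

    Computed as max(x, slope * x), valid for any slope < 1; preserves dtype.
    """
    x = np.asarray(x)
    return np.maximum(x, x * slope)


def leaky_relu_grad(x, slope: float = DEFAULT_LEAKY_SLOPE):
    x = np.asarray(x)
    one = x.dtype.type(1) if x.dtype.kind == "f" else 1.0
    return np.where(x > 0, one, x.dtype.type(slope) if x.dtype.kind == "f" else slope)


def leaky_relu_backward(dout, x, slope: float = DEFAULT_LEAKY_SLOPE, inplace: bool = False):
    """Chain-rule product dout * leaky_relu'(x) without dtype upcasts.

    With ``inplace=True`` the product overwrites ``dout`` (single masked
    pass; the training loop uses this on gradient buffers it owns).
    """
    if inplace:
        np.multiply(dout, dout.dtype.type(slope), where=(x <= 0), out=dout)
        return dout
    return np.where(x > 0, dout, dout * dout.dtype.type(slope))


@dataclass
class EdgeConvParams:
    """One edge-convolution layer: weight (D_out, D_in) and activation slope."""

    weight: np.ndarray
    leaky_slope: float = DEFAULT_LEAKY_SLOPE

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight)
        if self.weight.ndim != 2:
            raise ValueError("weight must be a 2-D matrix")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky_slope must lie in (0, 1)")


def aggregation_matrix(graph: NeighborGraph, dtype=np.float64) -> sp.csr_matrix:
    """Row-stochastic sparse matrix M with M x = mean over N(i) u {i}."""
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(graph.neighbor_lists):
        deg = len(nbrs) + 1
        w = 1.0 / deg
        rows.append(i)
        cols.append(i)
        vals.append(w)
        rows.extend([i] * len(nbrs))
        cols.extend(int(j) for j in nbrs)
        vals.extend([w] * len(nbrs))
    n = graph.n_nodes
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=dtype)


def edgeconv_layer(features: np.ndarray, graph: NeighborGraph,
                   params: EdgeConvParams) -> np.ndarray:
    """Apply one self-loop-normalized edge convolution with Leaky ReLU."""
    features = np.asarray(features)
    if features.ndim != 2 or features.shape[0] != graph.n_nodes:
        raise ValueError(
            f"features must be ({graph.n_nodes}, D), got {features.shape}"
        )
    if params.weight.shape[1] != features.shape[1]:
        raise ValueError(
            f"weight expects D_in={params.weight.shape[1]}, features have D={features.shape[1]}"
        )
    M = aggregation_matrix(graph, dtype=features.dtype)
    agg = M @ features
    return leaky_relu(agg @ params.weight.T, params.leaky_slope)


def stack_edgeconv(
    coords: np.ndarray,
    params_list: list[EdgeConvParams],
    init_features: np.ndarray | None = None,
    k: int = 8,
    dynamic: bool = False,
) -> list[np.ndarray]:
    """Run a stack of edge convolutions; returns all per-layer outputs.

    Layer 1 consumes ``init_features`` (the raw coordinates by default).
    With ``dynamic=False`` the spatial kNN graph built from ``coords`` is
    reused by every layer; with ``dynamic=True`` each subsequent layer
    rebuilds the kNN graph from the previous layer's output features.
    """
    if not params_list:
        raise ValueError("need at least one layer of parameters")
    coords = np.asarray(coords)
    features = coords if init_features is None else np.asarray(init_features)
    graph = knn_neighbors(coords, k)
    outputs = []
    for layer, params in enumerate(params_list):
        if dynamic and layer > 0:
            graph = _feature_knn(outputs[-1], k)
        features = edgeconv_layer(features, graph, params)
        outputs.append(features)
    return outputs


def _feature_knn(features: np.ndarray, k: int) -> NeighborGraph:
    """kNN graph in feature space (any dimensionality)."""
    from scipy.spatial.distance import cdist

    D = cdist(features, features)
    n = D.shape[0]
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    return NeighborGraph([order[i] for i in range(n)], n, "knn", float(k))


def receptive_field(graph: NeighborGraph, center_index: int, n_layers: int) -> set:
    """Nodes within graph distance <= n_layers of the center (BFS).

    Edges are taken undirected, matching how information flows through
    stacked aggregations over a symmetrized neighborhood structure.
    """
    if not 0 <= center_index < graph.n_nodes:
        raise ValueError("center_index out of range")
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    adj: list[set] = [set() for _ in range(graph.n_nodes)]
    for i, nbrs in enumerate(graph.neighbor_lists):
        for j in nbrs:
            adj[i].add(int(j))
            adj[int(j)].add(i)
    visited = {center_index}
    frontier = {center_index}
    for _ in range(n_layers):
        frontier = {j for i in frontier for j in adj[i]} - visited
        if not frontier:
            break
        visited |= frontier
    return visited
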