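"""Spatial neighborhood graph construction.

Edges are weighted by a Gaussian kernel of physical distance,
``A_ij = exp(-d(i,j)^2 / (2 lambda^2))``, restricted to the union of each
spot's k nearest neighbors and symmetrized by elementwise maximum.  The
GCN operator is the symmetric normalization ``D~^{-1/2}(A+I)D~^{-1/2}``.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp
from sklearn.neighbors import NearestNeighbors

from .datatypes import CoordinateTable, SpatialGraph

__all__ = [
    "auto_bandwidth",
    "build_spatial_graph",
    "normalize_adjacency",
    "build_block_diagonal",
    "export_edge_list",
]


def auto_bandwidth(positions: np.ndarray) -> float:
    """Median nearest-neighbor distance; the scale-free default bandwidth.

    Using lambda = median NN distance is equivalent to rescaling coordinates
    so that distance is 1 and taking lambda = 1.
    """
    nn = NearestNeighbors(n_neighbors=2).fit(positions)
    d, _ = nn.kneighbors(positions)
    med = float(np.median(d[:, 1]))
    return med if med > 0 else 1.0


def build_spatial_graph(
    coords: CoordinateTable | np.ndarray,
    lambda_: float | None = None,
    k_neighbors: int = 6,
) -> SpatialGraph:
    """Build the Gaussian-kernel kNN graph over spot coordinates.

    Parameters
    ----------
    coords
        Coordinate table or plain (N, 2) array.
    lambda_
        Kernel bandwidth; ``None`` uses the median nearest-neighbor distance.
    k_neighbors
        Each spot keeps its ``k_neighbors`` nearest spots; pass ``N - 1`` for
        the dense all-pairs kernel.

    Returns
    -------
    SpatialGraph with symmetric sparse ``weights`` and ``normalized`` filled.
    """
    if not isinstance(coords, CoordinateTable):
        coords = CoordinateTable(np.asarray(coords))
    pos = coords.positions
    n = pos.shape[0]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be positive")
    if n < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors + 1 = {k_neighbors + 1} spots, "
            f"got {n} ({k_neighbors + 1 - n} short)"
        )
    if lambda_ is None:
        lambda_ = auto_bandwidth(pos)
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pos)
    dist, idx = nn.kneighbors(pos)
    # drop the self column (first neighbor of each spot is itself at d=0;
    # with duplicate coordinates 'self' may land elsewhere in the row, so
    # remove one zero-distance self match explicitly)
    rows, cols, vals = [], [], []
    for i in range(n):
        neigh = idx[i]
        d = dist[i]
        self_pos = np.nonzero(neigh == i)[0]
        drop = self_pos[0] if len(self_pos) else 0
        keep = np.ones(len(neigh), dtype=bool)
        keep[drop] = False
        rows.extend([i] * k_neighbors)
        cols.extend(neigh[keep][:k_neighbors])
        vals.extend(np.exp(-d[keep][:k_neighbors] ** 2 / (2.0 * lambda_**2)))
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)  # mutual-max symmetrization of the directed kNN relation
    A.setdiag(0)
    A.eliminate_zeros()
    graph = SpatialGraph(weights=A, lambda_=float(lambda_), k_neighbors=k_neighbors)
    return normalize_adjacency(graph)


def normalize_adjacency(graph: SpatialGraph) -> SpatialGraph:
    """Fill ``graph.normalized`` with D~^{-1/2}(A + I)D~^{-1/2}."""
    A = sp.csr_matrix(graph.weights)
    n = A.shape[0]
    A_tilde = A + sp.identity(n, format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    graph.normalized = sp.csr_matrix(D @ A_tilde @ D)
    return graph


def build_block_diagonal(graphs: list[SpatialGraph]) -> SpatialGraph:
    """Assemble per-slice graphs into one graph with no cross-slice edges."""
    if not graphs:
        raise ValueError("need at least one graph")
    if len(graphs) == 1:
        return graphs[0]
    W = sp.block_diag([g.weights for g in graphs], format="csr")
    out = SpatialGraph(
        weights=W,
        lambda_=graphs[0].lambda_,
        k_neighbors=max(g.k_neighbors for g in graphs),
    )
    return normalize_adjacency(out)


def export_edge_list(graph: SpatialGraph) -> np.ndarray:
    """Upper-triangle edges as an (n_edges, 3) array of (i, j, weight)."""
    coo = sp.triu(graph.weights, k=1).tocoo()
    return np.column_stack([coo.row, coo.col, coo.data])
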