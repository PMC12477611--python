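"""Spatial clustering of the joint representation and partition agreement."""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import kneighbors_graph

from .datatypes import ClusteringResult

__all__ = ["cluster", "adjusted_rand_index"]


def cluster(Z: np.ndarray, method: str = "kmeans", k: int | None = None,
            resolution: float = 1.0, seed: int = 0,
            knn: int = 15, truth: np.ndarray | None = None) -> ClusteringResult:
    """Cluster spots in embedding space.

    ``kmeans`` (for a known number of domains k, 20 restarts) or ``louvain``
    (community detection on a kNN graph of Z at the given resolution, for an
    unknown number of domains).  If ``truth`` is given, the adjusted Rand
    index against it is attached to the result.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("embedding contains non-finite values")
    n = Z.shape[0]
    if method == "kmeans":
        if k is None:
            raise ValueError("kmeans requires k")
        if k > n:
            raise ValueError(f"k={k} exceeds {n} spots")
        km = KMeans(n_clusters=k, n_init=20, random_state=seed)
        labels = km.fit_predict(Z)
    elif method == "louvain":
        import igraph

        adj = kneighbors_graph(Z, n_neighbors=min(knn, n - 1),
                               include_self=False)
        adj = adj.maximum(adj.T).tocoo()
        edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
        g = igraph.Graph(n=n, edges=edges)
        part = g.community_multilevel(resolution=resolution)
        labels = np.asarray(part.membership)
    else:
        raise ValueError("method must be 'kmeans' or 'louvain'")
    result = ClusteringResult(labels=labels, method=method, k=k,
                              resolution=resolution if method == "louvain" else None)
    if truth is not None:
        result.ari = adjusted_rand_index(labels, truth)
    return result


def adjusted_rand_index(labels, truth) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError(
            f"partition lengths differ: {labels.shape[0]} vs {truth.shape[0]}")
    return float(adjusted_rand_score(truth, labels))
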