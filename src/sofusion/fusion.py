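"""Cross-omics fusion: intra-omics label loss, common-space projection,
commonality (Gram-alignment) loss, joint representation and the spatial
embedding regularizer.

The commonality loss compares the row-normalized Gram matrices of the two
modalities' common-space projections; it is invariant to right-orthogonal
transforms of either projection and is divided by N^2 so the value does not
grow with the number of spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse as sp

from . import _autodiff as ad

__all__ = [
    "FusionWeights",
    "FusionModule",
    "omics_label_loss",
    "project_common",
    "fuse_common",
    "commonality_loss",
    "combine_representations",
    "spatial_regularization",
    "embedding_bandwidth",
]


@dataclass
class FusionWeights:
    """Mixing weights of the joint representation Z = a*E_A1 + b*E_A2 + g*E_C."""

    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    gamma: float = 1.0 / 3.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("fusion weights must be non-negative")
        if self.alpha + self.beta + self.gamma <= 0:
            raise ValueError("fusion weights must not all be zero")


class FusionModule:
    """Learnable parameters of the inter-omics stage.

    Holds the per-modality common-space projections (ReLU affine maps
    g -> g), the affine fusion map (2g -> g) and the two-class omics-label
    head (g -> 2).
    """

    def __init__(self, g: int, rng: np.random.Generator):
        self.g = g
        self.W_C1 = ad.Parameter(ad.glorot(rng, g, g))
        self.b_C1 = ad.Parameter(np.zeros(g))
        self.W_C2 = ad.Parameter(ad.glorot(rng, g, g))
        self.b_C2 = ad.Parameter(np.zeros(g))
        self.W_E = ad.Parameter(ad.glorot(rng, 2 * g, g))
        self.b_E = ad.Parameter(np.zeros(g))
        self.W_y = ad.Parameter(ad.glorot(rng, g, 2))
        self.b_y = ad.Parameter(np.zeros(2))

    def parameters(self) -> list[ad.Parameter]:
        return [self.W_C1, self.b_C1, self.W_C2, self.b_C2,
                self.W_E, self.b_E, self.W_y, self.b_y]

    def project(self, E1: ad.Tensor, E2: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor]:
        return (
            ad.relu(E1 @ self.W_C1 + self.b_C1),
            ad.relu(E2 @ self.W_C2 + self.b_C2),
        )

    def fuse(self, C1: ad.Tensor, C2: ad.Tensor) -> ad.Tensor:
        return ad.concat([C1, C2], axis=1) @ self.W_E + self.b_E

    def label_loss(self, E_A1: ad.Tensor, E_A2: ad.Tensor) -> ad.Tensor:
        return omics_label_loss(E_A1, E_A2, head=(self.W_y, self.b_y))


def _t(x) -> ad.Tensor:
    return x if isinstance(x, ad.Tensor) else ad.Tensor(np.asarray(x, dtype=float))


def _maybe_item(out: ad.Tensor, inputs) -> float | ad.Tensor:
    if any(isinstance(x, ad.Tensor) for x in inputs):
        return out
    return float(out.data)


def omics_label_loss(E_A1, E_A2, head) -> float | ad.Tensor:
    """Mean two-class cross-entropy of a linear head predicting which
    modality each embedding row came from (label 0: modality 1; 1: modality 2).

    Minimized jointly with the encoders, this rewards embeddings that retain
    modality-specific structure (the head can still tell them apart).
    """
    E_A1_t, E_A2_t = _t(E_A1), _t(E_A2)
    if isinstance(head, tuple):
        W, b = head
    else:  # FusionModule-style object
        W, b = head.W_y, head.b_y
    W, b = _t(W), _t(b)
    n1, n2 = E_A1_t.shape[0], E_A2_t.shape[0]
    E_all = ad.concat([E_A1_t, E_A2_t], axis=0)
    logits = E_all @ W + b
    logp = ad.row_log_softmax(logits)
    onehot = np.zeros((n1 + n2, 2))
    onehot[:n1, 0] = 1.0
    onehot[n1:, 1] = 1.0
    loss = -(logp * ad.Tensor(onehot)).sum() * (1.0 / (n1 + n2))
    return _maybe_item(loss, (E_A1, E_A2, W if not isinstance(head, tuple) else head[0]))


def project_common(E, W_C, b_C) -> np.ndarray | ad.Tensor:
    """Map an embedding into the shared space: relu(E @ W_C + b_C)."""
    out = ad.relu(_t(E) @ _t(W_C) + _t(b_C))
    return out if isinstance(E, ad.Tensor) else out.data


def fuse_common(C1, C2, W_E, b_E) -> np.ndarray | ad.Tensor:
    """Affine fusion of the two common projections.

    ``W_E`` may be given as (g, 2g) acting on the concatenated column (the
    textbook orientation) or as (2g, g) acting on rows; both produce
    ``concat(C1, C2) @ W + b_E`` row-wise with no activation.
    """
    C1_t, C2_t = _t(C1), _t(C2)
    W = _t(W_E)
    two_g = C1_t.shape[1] + C2_t.shape[1]
    if W.shape[0] != two_g:
        W = W.T
    out = ad.concat([C1_t, C2_t], axis=1) @ W + _t(b_E)
    return out if isinstance(C1, ad.Tensor) else out.data


def _row_normalize(C: ad.Tensor, eps: float = 1e-12) -> ad.Tensor:
    norms = ((C * C).sum(axis=1, keepdims=True) + eps**2) ** 0.5
    return C / norms


def commonality_loss(C1, C2) -> float | ad.Tensor:
    """Squared Frobenius distance between row-normalized Gram matrices,
    divided by N^2.  Zero iff the two modalities induce the same pairwise
    cosine-similarity structure; zero rows normalize to zero rows."""
    C1_t, C2_t = _t(C1), _t(C2)
    n = C1_t.shape[0]
    A = _row_normalize(C1_t)
    B = _row_normalize(C2_t)
    # ||AA^T - BB^T||_F^2 = ||A^T A||^2 + ||B^T B||^2 - 2||A^T B||^2,
    # evaluated in g x g space instead of forming the N x N Gram matrices
    M11 = A.T @ A
    M22 = B.T @ B
    M12 = A.T @ B
    loss = ((M11 * M11).sum() + (M22 * M22).sum()
            - 2.0 * (M12 * M12).sum()) * (1.0 / n**2)
    return _maybe_item(loss, (C1, C2))


def combine_representations(E_A1, E_A2, E_C, w: FusionWeights):
    """Joint representation Z = alpha*E_A1 + beta*E_A2 + gamma*E_C."""
    shapes = {np.shape(x.data if isinstance(x, ad.Tensor) else x)
              for x in (E_A1, E_A2, E_C)}
    if len(shapes) != 1:
        raise ValueError(f"embedding shapes differ: {sorted(shapes)}")
    out = w.alpha * _t(E_A1) + w.beta * _t(E_A2) + w.gamma * _t(E_C)
    return out if isinstance(E_A1, ad.Tensor) else out.data


def embedding_bandwidth(Z: np.ndarray, max_rows: int = 1024) -> float:
    """Median pairwise embedding distance, the bandwidth of the similarity Q.

    Estimated on an evenly-strided subsample of at most ``max_rows`` rows so
    the cost stays quadratic in a constant.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n > max_rows:
        Z = Z[:: int(np.ceil(n / max_rows))]
    sq = np.sum(Z**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T, 0.0)
    iu = np.triu_indices(d2.shape[0], k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


def spatial_regularization(proximity, Z, sigma_z: float | None = None):
    """Penalize embedding dissimilarity between spatially related spots.

    ``proximity`` is a symmetric non-negative matrix with entries in [0, 1] —
    by default the Gaussian spatial kernel restricted to graph edges (sparse),
    so only retained neighbor pairs contribute.  The embedding similarity is
    ``Q_ij = exp(-||Z_i - Z_j||^2 / (2 sigma_z^2))`` with ``sigma_z`` the
    median pairwise embedding distance (held constant w.r.t. gradients).
    Returns ``sum_ij proximity_ij * (1 - Q_ij) / N^2``.
    """
    is_tensor = isinstance(Z, ad.Tensor)
    Z_t = _t(Z)
    n = Z_t.shape[0]
    if sigma_z is None:
        sigma_z = embedding_bandwidth(Z_t.data)
    inv = 1.0 / (2.0 * sigma_z**2)
    if sp.issparse(proximity):
        coo = proximity.tocoo()
        if coo.nnz == 0:
            return 0.0 if not is_tensor else ad.Tensor(0.0)
        zi = ad.gather_rows(Z_t, coo.row)
        zj = ad.gather_rows(Z_t, coo.col)
        d2 = ((zi - zj) * (zi - zj)).sum(axis=1)
        q = ad.exp(-1.0 * d2 * inv)
        w = ad.Tensor(coo.data)
        loss = (w * (1.0 - q)).sum() * (1.0 / n**2)
    else:
        P = np.asarray(proximity, dtype=float)
        sq = (Z_t * Z_t).sum(axis=1, keepdims=True)
        d2 = ad.clamp(sq + sq.T - 2.0 * (Z_t @ Z_t.T), lo=0.0)
        q = ad.exp(-1.0 * d2 * inv)
        loss = (ad.Tensor(P) * (1.0 - q)).sum() * (1.0 / n**2)
    return loss if is_tensor else float(loss.data)
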