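"""Per-modality graph-convolutional encoder and global self-attention.

Each GCN layer computes ``activation(S @ E @ W)`` where S is the
symmetric-normalized adjacency with self-loops; no bias term.  The
attention refinement is parameter-free:
``E_A = softmax(E E^T / sqrt(g)) E`` with row-wise softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

from . import _autodiff as ad
from .datatypes import ModalityEmbedding, OmicsMatrix, SpatialGraph

__all__ = ["EncoderConfig", "GCNEncoder", "gcn_layer", "gcn_encode",
           "self_attention", "attention_weights"]

_ACTIVATIONS = {
    "linear": lambda t: t,
    "relu": ad.relu,
    "elu": ad.elu,
}


@dataclass
class EncoderConfig:
    """Widths and activations of the GCN stack.

    hidden_dims: successive layer widths; the last entry is the latent
    dimension g.  Hidden layers use ``activation``; the output layer is linear.
    """

    hidden_dims: tuple[int, ...] = (256, 64)
    activation: str = "elu"
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.hidden_dims):
            raise ValueError("all layer widths must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def latent_dim(self) -> int:
        return self.hidden_dims[-1]


class GCNEncoder:
    """Stack of GCN layers with Glorot-initialized weights."""

    def __init__(self, in_dim: int, cfg: EncoderConfig, rng: np.random.Generator):
        dims = [in_dim, *cfg.hidden_dims]
        self.cfg = cfg
        self.weights = [
            ad.Parameter(ad.glorot(rng, dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]

    def parameters(self) -> list[ad.Parameter]:
        return list(self.weights)

    def forward(self, x: ad.Tensor, normalized: sp.spmatrix) -> ad.Tensor:
        h = x
        last = len(self.weights) - 1
        for li, W in enumerate(self.weights):
            act = "linear" if li == last else self.cfg.activation
            h = _ACTIVATIONS[act](ad.spmm(normalized, h) @ W)
            if not np.isfinite(h.data).all():
                raise FloatingPointError(f"non-finite values after GCN layer {li}")
        return h


def gcn_layer(
    E_in: np.ndarray,
    normalized: sp.spmatrix | np.ndarray,
    W: np.ndarray,
    activation: str = "linear",
) -> np.ndarray:
    """One GCN layer: activation(normalized @ E_in @ W)."""
    E_in = np.asarray(E_in, dtype=float)
    W = np.asarray(W, dtype=float)
    n = normalized.shape[0]
    if E_in.shape[0] != n:
        raise ValueError(f"E_in has {E_in.shape[0]} rows but graph has {n} spots")
    if E_in.shape[1] != W.shape[0]:
        raise ValueError(
            f"E_in has {E_in.shape[1]} columns but W expects {W.shape[0]} inputs"
        )
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    S = sp.csr_matrix(normalized) if sp.issparse(normalized) else np.asarray(normalized)
    out = _ACTIVATIONS[activation](ad.Tensor(S @ E_in) @ ad.Tensor(W))
    return out.data


def gcn_encode(
    x: OmicsMatrix | np.ndarray,
    graph: SpatialGraph,
    cfg: EncoderConfig | None = None,
) -> ModalityEmbedding:
    """Run a freshly initialized GCN stack forward; deterministic per seed."""
    cfg = cfg or EncoderConfig()
    data = x.encoded_input if isinstance(x, OmicsMatrix) else np.asarray(x, dtype=float)
    if graph.normalized is None:
        raise ValueError("graph.normalized not built; call normalize_adjacency first")
    rng = np.random.default_rng(cfg.seed)
    enc = GCNEncoder(data.shape[1], cfg, rng)
    E = enc.forward(ad.Tensor(data), graph.normalized).data
    return ModalityEmbedding(E=E)


def attention_weights(E: np.ndarray) -> np.ndarray:
    """The row-stochastic attention matrix ``softmax(E E^T / sqrt(g))``."""
    E = np.asarray(E, dtype=float)
    scores = E @ E.T / np.sqrt(E.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    return w / w.sum(axis=1, keepdims=True)


def self_attention(
    E: np.ndarray | ad.Tensor, block_size: int = 2048
) -> np.ndarray | ad.Tensor:
    """Global attention refinement ``softmax(E E^T / sqrt(g)) E``.

    For plain arrays the N x N score matrix is processed in row blocks of
    ``block_size`` so memory stays bounded; tensor inputs (used during
    training) go through the autodiff path in one piece.
    """
    if isinstance(E, ad.Tensor):
        g = E.shape[1]
        scores = (E @ E.T) * (1.0 / np.sqrt(g))
        return ad.row_softmax(scores) @ E
    E = np.asarray(E, dtype=float)
    n, g = E.shape
    out = np.empty_like(E)
    scale = 1.0 / np.sqrt(g)
    for start in range(0, n, block_size):
        block = E[start : start + block_size]
        scores = block @ E.T * scale
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        out[start : start + block_size] = w @ E
    return out
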