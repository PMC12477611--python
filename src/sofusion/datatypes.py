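"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

MODALITIES = ("rna", "atac", "adt", "other")


@dataclass
class CoordinateTable:
    """Physical spot/cell locations.

    positions : (N, 2) array in physical units, one row per spot.
    spot_ids  : N unique labels.
    slice_ids : optional N labels for multi-slice input.
    """

    positions: np.ndarray
    spot_ids: np.ndarray | None = None
    slice_ids: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError(f"positions must be N x 2, got {self.positions.shape}")
        if self.positions.shape[0] < 2:
            raise ValueError("at least 2 spots are required")
        if np.isnan(self.positions).any():
            raise ValueError("positions contain NaN")
        if self.spot_ids is None:
            self.spot_ids = np.array([f"spot_{i}" for i in range(len(self.positions))])
        else:
            self.spot_ids = np.asarray(self.spot_ids)
            if len(np.unique(self.spot_ids)) != len(self.spot_ids):
                raise ValueError("spot_ids must be unique")
        if self.slice_ids is not None:
            self.slice_ids = np.asarray(self.slice_ids)

    @property
    def n_spots(self) -> int:
        return self.positions.shape[0]


@dataclass
class SpatialGraph:
    """Gaussian-kernel weighted spot graph and its normalized GCN operator.

    weights    : symmetric non-negative sparse adjacency A (no self loops).
    lambda_    : kernel bandwidth actually used.
    k_neighbors: sparsification degree.
    normalized : D~^{-1/2} (A + I) D~^{-1/2}, filled by ``normalize_adjacency``.
    """

    weights: sp.csr_matrix
    lambda_: float
    k_neighbors: int
    normalized: sp.csr_matrix | None = None

    @property
    def n_spots(self) -> int:
        return self.weights.shape[0]


@dataclass
class OmicsMatrix:
    """One modality: raw decoder target plus the encoder-side transform."""

    raw: np.ndarray
    encoded_input: np.ndarray
    modality: str
    feature_ids: np.ndarray | None = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.encoded_input = np.asarray(self.encoded_input, dtype=float)
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if (self.raw < 0).any():
            raise ValueError("raw matrix has negative entries")
        if np.isnan(self.encoded_input).any():
            raise ValueError("encoded_input contains NaN")
        if self.raw.shape[0] != self.encoded_input.shape[0]:
            raise ValueError("raw and encoded_input row counts differ")
        if self.feature_ids is None:
            self.feature_ids = np.array([f"f{i}" for i in range(self.raw.shape[1])])
        else:
            self.feature_ids = np.asarray(self.feature_ids)

    @property
    def n_spots(self) -> int:
        return self.raw.shape[0]

    @property
    def n_features(self) -> int:
        return self.raw.shape[1]


@dataclass
class SpatialOmicsPair:
    """Two aligned modalities over the same spots, plus coordinates."""

    omics1: OmicsMatrix
    omics2: OmicsMatrix | None
    coords: CoordinateTable
    aligned: bool = True

    def __post_init__(self):
        n = self.coords.n_spots
        if self.omics1.n_spots != n:
            raise ValueError("omics1 row count does not match coordinates")
        if self.omics2 is not None and self.omics2.n_spots != n:
            raise ValueError("omics2 row count does not match coordinates")

    @property
    def n_spots(self) -> int:
        return self.coords.n_spots

    @property
    def modalities(self) -> list[OmicsMatrix]:
        return [m for m in (self.omics1, self.omics2) if m is not None]


@dataclass
class ModalityEmbedding:
    """Per-omics encoder outputs: GCN embedding E, attention-refined E_A,
    common-space projection C (filled by the fusion stage)."""

    E: np.ndarray
    E_A: np.ndarray | None = None
    C: np.ndarray | None = None


@dataclass
class JointRepresentation:
    """The fused N x g representation used for clustering."""

    Z: np.ndarray
    E_C: np.ndarray | None = None
    training_meta: dict = field(default_factory=dict)


@dataclass
class ClusteringResult:
    labels: np.ndarray
    method: str
    k: int | None = None
    resolution: float | None = None
    ari: float | None = None
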