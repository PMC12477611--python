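"""Per-modality standardization of raw matrices into encoder inputs.

The decoders always reconstruct raw-scale targets (counts, binary
accessibility, or [0,1]-scaled intensities); only the encoder side is
transformed.  Recipes follow field convention per modality:

- RNA  : library-size normalization, log1p, top highly-variable genes.
- ATAC : binarization, TF-IDF with idf = log(1 + N/df), per-peak unit scaling.
- ADT  : centered log-ratio across proteins within each spot.
- other: per-feature min-max scaling to [0, 1] (both encoder input and
  decoder target, as required by the elementwise cross-entropy decoder).
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_rna",
    "preprocess_atac",
    "preprocess_adt",
    "preprocess_other",
    "preprocess",
]


def _check_counts(raw: np.ndarray, what: str) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError(f"{what} counts must be non-negative")
    if not np.allclose(raw, np.round(raw)):
        raise ValueError(f"{what} counts must be integer-valued")
    return raw


def preprocess_rna(
    raw: np.ndarray,
    n_top_features: int = 3000,
    target_sum: float | None = None,
    feature_ids: np.ndarray | None = None,
) -> OmicsMatrix:
    """Log-normalize counts and keep the most variable genes.

    ``encoded_input = log1p(counts * target_sum / library_size)`` restricted to
    the ``n_top_features`` genes with the largest variance of the log-normalized
    values; ``raw`` is restricted to the same genes so the ZINB decoder sees
    aligned count targets.  ``target_sum=None`` uses the median library size.
    """
    raw = _check_counts(raw, "RNA")
    n, d = raw.shape
    lib = raw.sum(axis=1)
    n_zero = int((lib == 0).sum())
    if n_zero:
        logger.warning("%d all-zero spots kept with zero encoder rows", n_zero)
    if target_sum is None:
        nonzero = lib[lib > 0]
        target_sum = float(np.median(nonzero)) if nonzero.size else 1.0
    safe_lib = np.where(lib > 0, lib, 1.0)
    lognorm = np.log1p(raw * (target_sum / safe_lib)[:, None])

    if feature_ids is None:
        feature_ids = np.array([f"gene_{j}" for j in range(d)])
    if n_top_features < d:
        var = lognorm.var(axis=0)
        top = np.sort(np.argsort(var, kind="stable")[::-1][:n_top_features])
        raw = raw[:, top]
        lognorm = lognorm[:, top]
        feature_ids = np.asarray(feature_ids)[top]
    return OmicsMatrix(raw=raw, encoded_input=lognorm, modality="rna",
                       feature_ids=feature_ids)


def preprocess_atac(
    raw: np.ndarray, feature_ids: np.ndarray | None = None
) -> OmicsMatrix:
    """Binarize accessibility and TF-IDF-transform it for the encoder.

    Peaks open in no spot are dropped.  idf = log(1 + N/df); the transformed
    matrix is scaled per peak to unit variance.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("ATAC matrix must be non-negative")
    binary = (raw > 0).astype(float)
    n, d = binary.shape
    df = binary.sum(axis=0)
    keep = df > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%d empty peaks dropped", n_dropped)
    binary = binary[:, keep]
    df = df[keep]
    if feature_ids is None:
        feature_ids = np.array([f"peak_{j}" for j in range(d)])
    feature_ids = np.asarray(feature_ids)[keep]

    idf = np.log(1.0 + n / df)
    tfidf = binary * idf[None, :]
    sd = tfidf.std(axis=0)
    scaled = tfidf / np.where(sd > 0, sd, 1.0)[None, :]
    return OmicsMatrix(raw=binary, encoded_input=scaled, modality="atac",
                       feature_ids=feature_ids)


def preprocess_adt(
    raw: np.ndarray, feature_ids: np.ndarray | None = None
) -> OmicsMatrix:
    """Centered log-ratio across proteins per spot; raw counts untouched."""
    raw = _check_counts(raw, "ADT")
    logged = np.log1p(raw)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return OmicsMatrix(raw=raw, encoded_input=clr, modality="adt",
                       feature_ids=feature_ids)


def preprocess_other(
    raw: np.ndarray, feature_ids: np.ndarray | None = None
) -> OmicsMatrix:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0.

    The scaled matrix is both the encoder input and the decoder target of the
    universal cross-entropy decoder.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("matrix must be non-negative")
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning("%d constant features mapped to 0", int(constant.sum()))
    scaled = (raw - lo[None, :]) / np.where(constant, 1.0, span)[None, :]
    scaled[:, constant] = 0.0
    return OmicsMatrix(raw=scaled, encoded_input=scaled, modality="other",
                       feature_ids=feature_ids)


def preprocess(raw: np.ndarray, modality: str, **kwargs) -> OmicsMatrix:
    """Dispatch to the modality-specific recipe."""
    table = {
        "rna": preprocess_rna,
        "atac": preprocess_atac,
        "adt": preprocess_adt,
        "other": preprocess_other,
    }
    if modality not in table:
        raise ValueError(f"unknown modality {modality!r}")
    return table[modality](raw, **kwargs)
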