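"""Readers, writers and run configuration.

Accepted matrix containers: AnnData ``.h5ad``, MatrixMarket ``.mtx`` with
feature/barcode sidecar lists, and dense CSV (spots in rows, barcodes as the
index column).  Spots are aligned across modalities by barcode intersection,
never positionally.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse as sp

from .datatypes import CoordinateTable, SpatialOmicsPair
from .preprocessing import preprocess

logger = logging.getLogger(__name__)

__all__ = ["ModalityInput", "RunConfig", "load_run_config", "load_pair",
           "save_results", "write_bundle"]


@dataclass
class ModalityInput:
    path: str
    modality: str
    features: str | None = None   # MTX sidecar (one feature id per line)
    barcodes: str | None = None   # MTX sidecar (one barcode per line)
    n_top_features: int = 3000    # RNA only


@dataclass
class RunConfig:
    omics1: ModalityInput
    omics2: ModalityInput | None = None
    coordinates: str | None = None  # CSV with columns x,y[,slice], barcode index
    outdir: str = "sofusion_out"
    seed: int = 0
    k_neighbors: int = 6
    lambda_: float | None = None
    model: dict = field(default_factory=dict)  # extra SoFusion kwargs

    def __post_init__(self):
        if self.omics1 is None:
            raise ValueError("at least one modality must be configured")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration with full defaulting."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    om1 = ModalityInput(**raw["omics1"])
    om2 = ModalityInput(**raw["omics2"]) if "omics2" in raw else None
    keys = {"coordinates", "outdir", "seed", "k_neighbors", "lambda_", "model"}
    rest = {k: v for k, v in raw.items() if k in keys}
    cfg = RunConfig(omics1=om1, omics2=om2, **rest)
    base = Path(path).parent
    for om in (cfg.omics1, cfg.omics2):
        if om is None:
            continue
        for attr in ("path", "features", "barcodes"):
            val = getattr(om, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(om, attr, str(base / val))
    if cfg.coordinates and not Path(cfg.coordinates).is_absolute():
        cfg.coordinates = str(base / cfg.coordinates)
    return cfg


# -- matrix readers ------------------------------------------------------------

def _read_matrix(inp: ModalityInput):
    """Return (dense matrix spots x features, barcodes, features, coords|None)."""
    path = Path(inp.path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    coords = None
    if suffix == ".h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        barcodes = adata.obs_names.to_numpy()
        features = adata.var_names.to_numpy()
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
    elif suffix == ".mtx":
        M = spio.mmread(path)
        X = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
        if inp.barcodes is None or inp.features is None:
            raise ValueError("MTX input requires barcodes and features sidecars")
        barcodes = pd.read_csv(inp.barcodes, header=None)[0].to_numpy()
        features = pd.read_csv(inp.features, header=None)[0].to_numpy()
        if X.shape == (len(features), len(barcodes)) and X.shape[0] != X.shape[1]:
            X = X.T  # features-by-barcodes orientation (CellRanger-style)
    elif suffix in (".csv", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        X = df.to_numpy(dtype=float)
        barcodes = df.index.to_numpy().astype(str)
        features = df.columns.to_numpy()
    else:
        raise ValueError(f"unsupported matrix format {suffix!r}")
    if X.shape[0] != len(barcodes):
        raise ValueError(f"{path}: matrix rows ({X.shape[0]}) != barcodes "
                         f"({len(barcodes)})")
    return X, np.asarray(barcodes).astype(str), np.asarray(features), coords


def _read_coordinates(path: str | Path):
    """CSV/TSV with barcode index and columns x, y (and optional slice)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        pos = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    else:
        pos = df.iloc[:, :2].to_numpy(dtype=float)
    slices = df[cols["slice"]].to_numpy() if "slice" in cols else None
    return pos, df.index.to_numpy().astype(str), slices


def load_pair(cfg: RunConfig) -> SpatialOmicsPair:
    """Read, align and preprocess the configured modalities.

    Spot barcodes are intersected across all inputs (and the coordinate
    table); retained spots follow modality 1's order; dropped spots are
    logged per input.
    """
    X1, bc1, feat1, coords1 = _read_matrix(cfg.omics1)
    inputs = [(cfg.omics1, X1, bc1, feat1)]
    shared = pd.Index(bc1)
    if cfg.omics2 is not None:
        X2, bc2, feat2, coords2 = _read_matrix(cfg.omics2)
        inputs.append((cfg.omics2, X2, bc2, feat2))
        shared = shared.intersection(pd.Index(bc2))
    if cfg.coordinates:
        pos, cbc, slices = _read_coordinates(cfg.coordinates)
        shared = shared.intersection(pd.Index(cbc))
    else:
        if coords1 is None:
            raise ValueError("no coordinate source: give a coordinates CSV or "
                             "an h5ad with obsm['spatial']")
        pos, cbc, slices = coords1, bc1, None
    if len(shared) == 0:
        raise ValueError("no shared barcodes across inputs")
    order = [b for b in bc1 if b in set(shared)]  # canonical: omics1 order

    omics = []
    for inp, X, bc, feat in inputs:
        idx = pd.Index(bc).get_indexer(order)
        dropped = len(bc) - len(order)
        if dropped:
            logger.warning("%s: dropped %d of %d spots not shared",
                           inp.path, dropped, len(bc))
        kwargs = {"feature_ids": feat}
        if inp.modality == "rna":
            kwargs["n_top_features"] = inp.n_top_features
        omics.append(preprocess(X[idx], inp.modality, **kwargs))

    cidx = pd.Index(cbc).get_indexer(order)
    if (cidx < 0).any():
        raise ValueError("coordinates missing for retained spots")
    coords = CoordinateTable(positions=pos[cidx], spot_ids=np.asarray(order),
                             slice_ids=None if slices is None else slices[cidx])
    return SpatialOmicsPair(omics1=omics[0],
                            omics2=omics[1] if len(omics) > 1 else None,
                            coords=coords, aligned=True)


# -- writers -------------------------------------------------------------------

def _config_hash(cfg_dict: dict) -> str:
    blob = json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_results(Z: np.ndarray, labels: np.ndarray | None, cfg: RunConfig,
                 spot_ids: np.ndarray | None = None,
                 loss_trace: list[dict] | None = None) -> dict:
    """Write the embedding, labels, loss trace, resolved config and a
    reproducibility manifest under ``cfg.outdir``; returns the path map."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    Z = np.asarray(Z)
    n = Z.shape[0]
    ids = (np.asarray(spot_ids) if spot_ids is not None
           else np.array([f"spot_{i}" for i in range(n)]))
    paths = {}

    paths["embedding_npz"] = outdir / "embedding.npz"
    np.savez(paths["embedding_npz"], Z=Z, spot_ids=ids)
    paths["embedding_csv"] = outdir / "embedding.csv"
    pd.DataFrame(Z, index=ids).to_csv(paths["embedding_csv"])

    if labels is not None:
        paths["labels_csv"] = outdir / "labels.csv"
        pd.DataFrame({"label": np.asarray(labels)}, index=ids).to_csv(
            paths["labels_csv"], index_label="spot_id")

    if loss_trace:
        paths["loss_trace_csv"] = outdir / "loss_trace.csv"
        pd.DataFrame(loss_trace).to_csv(paths["loss_trace_csv"], index=False)

    cfg_dict = asdict(cfg)
    paths["config_json"] = outdir / "resolved_config.json"
    with open(paths["config_json"], "w") as fh:
        json.dump(cfg_dict, fh, indent=2, default=str)

    import sklearn

    manifest = {
        "package": "sofusion",
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": __import__("scipy").__version__,
        "sklearn": sklearn.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg_dict),
        "n_spots": int(n),
        "latent_dim": int(Z.shape[1]),
    }
    paths["manifest_json"] = outdir / "manifest.json"
    with open(paths["manifest_json"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def write_bundle(bundle, outdir: str | Path) -> dict:
    """Write a synthetic bundle as one h5ad per modality plus truth labels."""
    import anndata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = bundle.pair
    ids = pair.coords.spot_ids.astype(str)
    paths = {}
    for i, om in enumerate(pair.modalities, start=1):
        ad_obj = anndata.AnnData(
            X=om.raw, obs=pd.DataFrame(index=ids),
            var=pd.DataFrame(index=om.feature_ids.astype(str)))
        ad_obj.obsm["spatial"] = pair.coords.positions
        p = outdir / f"omics{i}_{om.modality}.h5ad"
        ad_obj.write_h5ad(p)
        paths[f"omics{i}"] = str(p)
    truth = outdir / "truth_labels.csv"
    pd.DataFrame({"domain": bundle.truth_labels}, index=ids).to_csv(
        truth, index_label="spot_id")
    paths["truth"] = str(truth)
    coords_csv = outdir / "coordinates.csv"
    pd.DataFrame(pair.coords.positions, columns=["x", "y"], index=ids).to_csv(
        coords_csv, index_label="spot_id")
    paths["coordinates"] = str(coords_csv)
    return paths
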