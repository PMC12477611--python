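"""Joint training of the fusion model and extraction of the spatial
representation.

`SoFusion` is a transductive representation learner in the scikit-learn
estimator idiom: construct with hyperparameters, ``fit`` on a
:class:`~sofusion.datatypes.SpatialOmicsPair`, read the fused embedding from
``embedding_`` (or ``fit_transform``).  Training is full batch: one forward
pass per epoch through the per-modality GCN encoders, the parameter-free
attention refinement, the common-space fusion, and the omics-specific
decoders, optimizing

    L = a * L_CE + b * L_con + c * L_reg + d * L_Recon

with all weights defaulting to 1.  The ADT decoder samples its background
intensity during training (reparameterized log-normal) and uses the analytic
log-normal mean at evaluation, so the returned embedding is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from .datatypes import JointRepresentation, SpatialGraph, SpatialOmicsPair
from .decoders import (ADTDecoder, BernoulliDecoder, UniversalDecoder,
                       ZINBDecoder, fit_gmm_prior, total_reconstruction_loss)
from .encoder import EncoderConfig, GCNEncoder, self_attention
from .fusion import (FusionModule, FusionWeights, combine_representations,
                     spatial_regularization)
from .graph import build_spatial_graph

__all__ = ["LossWeights", "TrainConfig", "SoFusion", "train",
           "single_modality_mode", "total_loss"]


@dataclass
class LossWeights:
    """Weights a, b, c, d of the label, commonality, spatial and
    reconstruction terms; the model default is 1 for each."""

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    d: float = 1.0

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class TrainConfig:
    epochs: int = 300
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"
    eval_every: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


def total_loss(parts: dict, w: LossWeights):
    """Weighted sum a*L_CE + b*L_con + c*L_reg + d*L_Recon.

    ``parts`` maps name -> scalar (float or autodiff tensor); missing parts
    count as 0.  A NaN part raises, naming the offending term.
    """
    weights = {"label": w.a, "commonality": w.b, "spatial": w.c,
               "reconstruction": w.d}
    total = None
    for name, weight in weights.items():
        part = parts.get(name)
        if part is None:
            continue
        val = part.data if isinstance(part, ad.Tensor) else part
        if not np.isfinite(val).all():
            raise FloatingPointError(f"loss part {name!r} is non-finite")
        term = weight * part
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no loss parts provided")
    return total


_DECODERS = {
    "rna": ZINBDecoder,
    "atac": BernoulliDecoder,
    "adt": ADTDecoder,
    "other": UniversalDecoder,
}


class SoFusion(BaseEstimator):
    """Spatial multi-omics fusion estimator.

    Parameters
    ----------
    hidden_dims : GCN layer widths; the last entry is the latent dimension g.
    k_neighbors, lambda_ : spatial graph sparsity and Gaussian bandwidth
        (``lambda_=None`` uses the median nearest-neighbor distance).
    alpha, beta, gamma : mixing weights of Z = alpha*E_A1 + beta*E_A2 + gamma*E_C.
    loss_a..loss_d : weights of the label, commonality, spatial and
        reconstruction losses.
    kl_weight : weight of the ADT background posterior/prior KL term.
    spatial_mode : "kernel" sums the regularizer over graph edges weighted by
        the Gaussian spatial kernel; "literal" uses the dense Euclidean
        distance matrix as the pair weight.
    modalities : "both", or 1 / 2 to train on a single modality (the joint
        representation is then that modality's attention output and the
        cross-omics losses are disabled).

    Attributes (after fit)
    ----------------------
    embedding_ : (N, g) fused representation Z.
    graph_ : the spatial graph used.
    loss_trace_ : per-epoch loss parts, list of dicts.
    """

    def __init__(self, hidden_dims=(256, 64), activation="elu",
                 k_neighbors=6, lambda_=None,
                 alpha=1 / 3, beta=1 / 3, gamma=1 / 3,
                 loss_a=1.0, loss_b=1.0, loss_c=1.0, loss_d=1.0,
                 kl_weight=1.0, decoder_hidden=64,
                 spatial_mode="kernel", modalities="both",
                 epochs=300, lr=1e-3, random_state=0):
        self.hidden_dims = hidden_dims
        self.activation = activation
        self.k_neighbors = k_neighbors
        self.lambda_ = lambda_
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.loss_a = loss_a
        self.loss_b = loss_b
        self.loss_c = loss_c
        self.loss_d = loss_d
        self.kl_weight = kl_weight
        self.decoder_hidden = decoder_hidden
        self.spatial_mode = spatial_mode
        self.modalities = modalities
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    # ------------------------------------------------------------------ setup
    def _active(self, pair: SpatialOmicsPair):
        if self.modalities == "both":
            if pair.omics2 is None:
                return [pair.omics1]
            return [pair.omics1, pair.omics2]
        idx = int(self.modalities)
        if idx not in (1, 2):
            raise ValueError("modalities must be 'both', 1 or 2")
        om = pair.omics1 if idx == 1 else pair.omics2
        if om is None:
            raise ValueError(f"modality {idx} missing from the pair")
        return [om]

    def _build(self, pair, graph, rng):
        cfg = EncoderConfig(hidden_dims=tuple(self.hidden_dims),
                            activation=self.activation)
        active = self._active(pair)
        self._encoders = [GCNEncoder(m.encoded_input.shape[1], cfg, rng)
                          for m in active]
        g = cfg.latent_dim
        self._fusion = FusionModule(g, rng) if len(active) == 2 else None
        self._decoders = []
        for m in active:
            cls = _DECODERS[m.modality]
            if m.modality == "adt":
                prior = fit_gmm_prior(m.raw, seed=self.random_state)
                dec = cls(rng, g, m.n_features, prior,
                          hidden_dim=self.decoder_hidden)
            else:
                dec = cls(rng, g, m.n_features, hidden_dim=self.decoder_hidden)
            self._decoders.append(dec)
        params = []
        for enc in self._encoders:
            params += enc.parameters()
        if self._fusion is not None:
            params += self._fusion.parameters()
        for dec in self._decoders:
            params += dec.parameters()
        return active, params

    def _spatial_weight_matrix(self, graph: SpatialGraph, coords):
        if self.spatial_mode == "kernel":
            return graph.weights
        if self.spatial_mode == "literal":
            pos = coords.positions
            return np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        raise ValueError("spatial_mode must be 'kernel' or 'literal'")

    # ---------------------------------------------------------------- forward
    def _forward(self, active, graph, sample, rng):
        embeds = []
        for enc, m in zip(self._encoders, active):
            E = enc.forward(ad.Tensor(m.encoded_input), graph.normalized)
            embeds.append(E)
        attns = [self_attention(E) for E in embeds]
        parts = {}
        if len(active) == 2:
            C1, C2 = self._fusion.project(embeds[0], embeds[1])
            E_C = self._fusion.fuse(C1, C2)
            parts["label"] = self._fusion.label_loss(attns[0], attns[1])
            from .fusion import commonality_loss
            parts["commonality"] = commonality_loss(C1, C2)
            Z = combine_representations(
                attns[0], attns[1], E_C,
                FusionWeights(self.alpha, self.beta, self.gamma))
        else:
            Z = attns[0]
        recon = []
        for dec, m in zip(self._decoders, active):
            target = m.raw
            if isinstance(dec, ADTDecoder):
                recon.append(dec.loss(target, Z, sample=sample, rng=rng,
                                      kl_weight=self.kl_weight))
            else:
                recon.append(dec.loss(target, Z))
        parts["reconstruction"] = total_reconstruction_loss(recon)
        parts["spatial"] = spatial_regularization(self._prox, Z)
        return Z, parts

    # -------------------------------------------------------------------- fit
    def fit(self, pair: SpatialOmicsPair, graph: SpatialGraph | None = None):
        for m in pair.modalities:
            if not np.isfinite(m.encoded_input).all():
                raise ValueError(f"{m.modality} encoder input has non-finite values")
        if graph is None:
            graph = build_spatial_graph(pair.coords, lambda_=self.lambda_,
                                        k_neighbors=self.k_neighbors)
        rng = np.random.default_rng(self.random_state)
        sample_rng = np.random.default_rng(
            np.random.SeedSequence(self.random_state).spawn(1)[0])
        active, params = self._build(pair, graph, rng)
        self._prox = self._spatial_weight_matrix(graph, pair.coords)
        single = len(active) == 1
        w = LossWeights(a=0.0 if single else self.loss_a,
                        b=0.0 if single else self.loss_b,
                        c=self.loss_c, d=self.loss_d)
        opt = ad.Adam(params, lr=self.lr)
        trace = []
        for epoch in range(self.epochs):
            opt.zero_grad()
            _, parts = self._forward(active, graph, sample=True, rng=sample_rng)
            try:
                loss = total_loss(parts, w)
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"{err} at epoch {epoch}; last finite epoch "
                    f"{epoch - 1}") from err
            loss.backward()
            opt.step()
            rec = {k: float(v.data) if isinstance(v, ad.Tensor) else float(v)
                   for k, v in parts.items()}
            rec["total"] = float(loss.data)
            rec["epoch"] = epoch
            trace.append(rec)
        Z, _ = self._forward(active, graph, sample=False, rng=None)
        self.embedding_ = Z.data if isinstance(Z, ad.Tensor) else Z
        self.graph_ = graph
        self.loss_trace_ = trace
        self.n_spots_ = pair.n_spots
        return self

    def fit_transform(self, pair: SpatialOmicsPair,
                      graph: SpatialGraph | None = None) -> np.ndarray:
        return self.fit(pair, graph).embedding_

    def transform(self, pair: SpatialOmicsPair) -> np.ndarray:
        """Return the embedding of the fitted data (transductive model)."""
        if not hasattr(self, "embedding_"):
            raise RuntimeError("estimator is not fitted")
        if pair.n_spots != self.n_spots_:
            raise ValueError("transform only supports the data used in fit")
        return self.embedding_


def train(pair: SpatialOmicsPair, graph: SpatialGraph | None = None,
          enc_cfg: EncoderConfig | None = None,
          fusion_w: FusionWeights | None = None,
          loss_w: LossWeights | None = None,
          train_cfg: TrainConfig | None = None) -> JointRepresentation:
    """Functional wrapper over :class:`SoFusion`."""
    enc_cfg = enc_cfg or EncoderConfig()
    fusion_w = fusion_w or FusionWeights()
    loss_w = loss_w or LossWeights()
    train_cfg = train_cfg or TrainConfig()
    est = SoFusion(hidden_dims=enc_cfg.hidden_dims, activation=enc_cfg.activation,
                   alpha=fusion_w.alpha, beta=fusion_w.beta, gamma=fusion_w.gamma,
                   loss_a=loss_w.a, loss_b=loss_w.b, loss_c=loss_w.c,
                   loss_d=loss_w.d, epochs=train_cfg.epochs, lr=train_cfg.lr,
                   random_state=train_cfg.seed)
    est.fit(pair, graph)
    return JointRepresentation(Z=est.embedding_,
                               training_meta={"loss_trace": est.loss_trace_,
                                              "epochs": train_cfg.epochs})


def single_modality_mode(pair: SpatialOmicsPair, which: int = 1,
                         **kwargs) -> JointRepresentation:
    """Train the same architecture on one modality only: the joint
    representation is that modality's attention-refined embedding and the
    cross-omics (label and commonality) losses are disabled."""
    est = SoFusion(modalities=which, **kwargs)
    est.fit(pair)
    return JointRepresentation(Z=est.embedding_,
                               training_meta={"loss_trace": est.loss_trace_})
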