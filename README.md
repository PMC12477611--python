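# sofusion

Spatial multi-omics technologies measure two molecular layers — e.g.
transcriptome + surface proteins (ADT), or transcriptome + chromatin
accessibility (ATAC) — at the same spatially barcoded spots of a tissue
section. Neither layer alone resolves all tissue domains: structure visible
in protein abundance may be invisible in RNA and vice versa. `sofusion`
learns a **joint low-dimensional representation** of two such modalities
that respects both molecular content and spatial context, for **spatial
domain identification** by clustering.

## Model

Given feature matrices $X_1 \in \mathbb{R}^{N\times d_1}$,
$X_2 \in \mathbb{R}^{N\times d_2}$ over the same $N$ spots and coordinates
$M \in \mathbb{R}^{N\times 2}$:

1. **Spatial graph.** Edge weights
   $A_{ij} = \exp(-d(i,j)^2 / 2\lambda^2)$ on each spot's $k$ nearest
   neighbors (default $k=6$, $\lambda$ = median nearest-neighbor distance),
   symmetrized; GCN operator $\tilde{D}^{-1/2}(A+I)\tilde{D}^{-1/2}$.
2. **Per-modality encoders.** Two-layer GCNs
   $E^{(l+1)} = \sigma(\tilde D^{-1/2}\tilde A \tilde D^{-1/2} E^{(l)} W^{(l)})$
   produce $E_1, E_2 \in \mathbb{R}^{N\times g}$, refined by parameter-free
   global attention $E_A = \mathrm{softmax}(EE^\top/\sqrt{g})\,E$.
3. **Cross-omics fusion.** ReLU projections $C_m$ into a common space, an
   affine fusion $E_C$ of their concatenation, a **commonality loss**
   $L_{con} = \lVert \tilde C_1\tilde C_1^\top - \tilde C_2\tilde C_2^\top
   \rVert_F^2 / N^2$ (row-normalized Gram alignment), and an **omics-label
   loss** $L_{CE}$: a linear head predicts which modality each embedding row
   came from, rewarding modality-specific structure.
4. **Joint representation.** $Z = \alpha E_{A1} + \beta E_{A2} + \gamma E_C$
   (defaults $1/3$ each), with a **spatial regularizer**
   $L_{reg} = \sum_{ij} A_{ij}(1-Q_{ij})/N^2$ pulling spatial neighbors
   together in embedding space
   ($Q_{ij} = \exp(-\lVert Z_i - Z_j\rVert^2/2\sigma_z^2)$).
5. **Omics-specific decoders** reconstruct raw-scale data from $Z$:
   zero-inflated negative binomial for RNA counts, Bernoulli for binarized
   accessibility, a two-component negative-binomial mixture with a
   GMM-initialized log-normal background prior for ADT counts (the
   foreground mean is constrained to exceed the background,
   $\nu^f = (1+\alpha^{ADT})\nu^b$), and a universal sigmoid/cross-entropy
   decoder for any other non-negative modality.

Training minimizes $L = a\,L_{CE} + b\,L_{con} + c\,L_{reg} + d\,L_{Recon}$
(all weights default to 1) full-batch with Adam. Domains are then found by
K-means (known domain count) or Louvain (unknown) on $Z$.

All differentiable computation runs on a compact reverse-mode autodiff
engine over numpy (`sofusion._autodiff`) — no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from sofusion import SoFusion, cluster, make_smoke_bundle

bundle = make_smoke_bundle(seed=0)          # 500 spots, 2 striped domains,
                                            # paired RNA (ZINB) + ADT (NB mix)
est = SoFusion(epochs=50, random_state=0)
Z = est.fit_transform(bundle.pair)          # (500, 64) joint representation
res = cluster(Z, method="kmeans", k=2, seed=0, truth=bundle.truth_labels)
print(f"spots: {bundle.pair.n_spots}, latent dim: {Z.shape[1]}")
print(f"initial total loss: {est.loss_trace_[0]['total']:.1f}")
print(f"final total loss:   {est.loss_trace_[-1]['total']:.1f}")
print(f"K-means ARI vs ground truth: {res.ari:.3f}")
```

Output:

```
spots: 500, latent dim: 64
initial total loss: 327491.8
final total loss:   233674.4
K-means ARI vs ground truth: 1.000
```

The loss (dominated by the ZINB + NB-mixture reconstruction terms) falls by
~30% over 50 epochs, and K-means on the fused embedding recovers the two
planted spatial domains exactly (ARI = 1).

The `sofusion` command-line tool exposes the same pipeline over files
(`sofusion run cfg.toml --k 5`, `sofusion simulate`, `sofusion cluster`,
`sofusion eval`); inputs may be `.h5ad`, MatrixMarket triplets, or dense
CSV, with coordinates embedded or in a separate CSV.

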