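# Methods

## Problem setting and model

`sofusion` addresses spatial domain identification from paired spatial
omics: two spot-by-feature matrices measured at the same $N$ spatial
locations, plus coordinates. The model is a graph-convolutional
autoencoder with cross-modal fusion; its output is a single $N \times g$
representation $Z$ (default $g = 64$) intended for clustering into
spatially coherent domains.

Assumptions worth stating explicitly:

- **Spatial smoothness.** Nearby spots tend to share a domain. This enters
  twice: through GCN message passing over the spatial graph, and through
  the spatial regularizer on $Z$.
- **Distributional forms.** RNA counts are ZINB; binarized accessibility is
  Bernoulli; protein counts are a two-component negative-binomial mixture
  (nonspecific background binding vs true signal) whose background
  intensity is log-normal. "Other" modalities are only assumed reducible
  to $[0,1]$ per feature.
- **Shared structure plus modality-specific structure.** The commonality
  loss aligns the two modalities' pairwise cosine-similarity (Gram)
  structure in a learned common space; the omics-label loss keeps the
  attention-refined embeddings modality-separable, preserving information
  that only one modality carries. These two pressures are complementary,
  not contradictory: one acts on the common projections, the other on the
  per-modality embeddings.

## Spatial graph

$A_{ij} = \exp(-d(i,j)^2/2\lambda^2)$ restricted to k-nearest neighbors and
symmetrized by elementwise maximum (an undirected graph). Defaults:
$k = 6$ (matching hexagonal Visium-like neighborhoods) and $\lambda$ equal
to the median nearest-neighbor distance, which makes the default scale-free
(equivalent to rescaling coordinates so that distance is 1 and taking
$\lambda = 1$). The kernel is defined over all pairs; sparsification is a
memory choice, and dense behaviour is available with `k_neighbors = N - 1`.
Self-loops enter only through the GCN normalization
$\tilde D^{-1/2}(A+I)\tilde D^{-1/2}$, never in $A$. Multi-slice input is
assembled block-diagonally (no cross-slice edges); normalization commutes
with assembly, which the tests check directly.

## Encoder and attention

Two GCN layers (widths 256 → 64, ELU on hidden, linear output, no bias, as
the propagation rule has none), Glorot-initialized from one run-level RNG.
The attention refinement $E_A = \mathrm{softmax}(EE^\top/\sqrt g)E$ is
parameter-free — no learned query/key/value maps — and is computed with a
row-max-stabilized softmax, in row blocks for plain-array use so the
$N \times N$ score matrix never exceeds a bounded block.

## Fusion stage

- Common projections use ReLU.
- The fusion map on the concatenated projections is affine with no
  activation.
- The commonality loss compares **row-normalized** Gram matrices and is
  divided by $N^2$ so its scale is independent of the number of spots. It
  is evaluated via the trace identity
  $\lVert AA^\top - BB^\top\rVert_F^2 = \lVert A^\top A\rVert_F^2 +
  \lVert B^\top B\rVert_F^2 - 2\lVert A^\top B\rVert_F^2$, i.e. in
  $g \times g$ space, which avoids materializing $N \times N$ matrices.
- The omics-label loss is a cooperative (jointly minimized) two-class
  cross-entropy: head and encoders descend the same objective, which
  rewards embeddings the head can classify — i.e. modality-separable
  embeddings. It is not adversarial.
- Spatial regularizer: the pair weight is the Gaussian **proximity kernel**
  of the spatial graph, so spatially close but embedding-distant pairs are
  penalized. Weighting by raw Euclidean distance instead (available via
  `spatial_mode="literal"`) would penalize the most *distant* pairs most
  strongly, which contradicts the regularizer's purpose; the kernel form is
  therefore the default. The embedding similarity is
  $Q_{ij} = \exp(-\lVert Z_i - Z_j\rVert^2 / 2\sigma_z^2)$ with $\sigma_z$
  the median pairwise embedding distance, held constant with respect to
  gradients and estimated on an evenly strided subsample of at most 1024
  rows. The sum runs over retained graph edges (off-edge kernel entries
  are exactly zero after sparsification); with a dense proximity matrix the
  all-pairs sum is computed via matrix products.

## Decoders

All likelihoods are evaluated in log space; mixtures use log-sum-exp. The
negative binomial is in mean-dispersion form,
$\mathrm{Var} = \mu + \mu^2/\theta$.

- **ZINB (RNA).** $\pi = \mathrm{sigmoid}$, $\mu, \theta = \exp$ heads on a
  shared one-layer ELU trunk; $\exp$ outputs clamped to $[10^{-5}, 10^6]$,
  probabilities to $[10^{-7}, 1-10^{-7}]$. The loss is the standard
  $-\sum_i \log \mathrm{ZINB}(x_i)$ (the per-spot log-likelihood sum).
- **Bernoulli (ATAC).** Sigmoid head, binary cross-entropy against the
  binarized matrix.
- **NB mixture (ADT).** The background mean $\nu^b$ has a log-normal
  posterior $(m^b, \sigma^b)$ predicted per spot and a log-normal prior
  initialized per protein from the lower-mean component of a two-component
  GMM on $\log(1+x)$; both prior parameters remain trainable. During
  training $\nu^b$ is sampled by reparameterization
  ($\exp(m^b + \sigma^b\varepsilon)$); at evaluation the analytic log-normal
  mean $\exp(m^b + (\sigma^b)^2/2)$ is used, so the returned embedding and
  parameters are deterministic. The foreground is
  $\nu^f = (1 + \mathrm{softplus}(\cdot))\,\nu^b \ge \nu^b$. A closed-form
  Gaussian KL (log scale) between posterior and prior is added with weight
  1 (configurable, including 0); the mixture NLL itself contains no
  sampling. The per-protein dispersion $\varphi$ is stored as a trainable
  log-value initialized at 0.
- **Universal decoder.** Sigmoid reconstruction with elementwise
  cross-entropy; requires targets in $[0,1]$, which `preprocess_other`
  guarantees.

The total reconstruction loss is the plain sum over active modalities, and
the overall objective is $L = aL_{CE} + bL_{con} + cL_{reg} + dL_{Recon}$
with defaults $a=b=c=d=1$.

## Preprocessing

Encoder inputs are transformed per field convention; decoders always see
raw-scale targets (counts or binary), since the likelihoods are only
meaningful there. RNA: library-size normalization to the median library,
$\log(1+\cdot)$, top highly variable genes by log-scale variance (default
3000); no size factors enter the ZINB mean — library effects are handled
on the encoder side only. ATAC: binarize, TF-IDF with
$\mathrm{idf} = \log(1 + N/\mathrm{df})$, per-peak unit variance. ADT:
centered log-ratio per spot. Other: per-feature min-max to $[0,1]$, which
doubles as the decoder target. Each recipe is overridable by preprocessing
the raw matrices yourself and constructing `OmicsMatrix` directly.

## Training and clustering

Full-batch Adam (lr $10^{-3}$), fixed epoch count (default 300), no early
stopping — the simplest reproducible contract. All gradients flow through
an in-repo reverse-mode autodiff engine over float64 numpy arrays
(`sofusion/_autodiff.py`): dense/sparse matrix products, the elementwise
transcendental functions the likelihoods need (including `lgamma` with
digamma gradient), row softmax, gather/concat, and clamping with zero
gradient outside the range. Gradient correctness is tested against central
finite differences for every operation and for each likelihood.

Single-modality mode trains one encoder/decoder with the cross-omics
(label and commonality) losses disabled; $Z$ is that modality's attention
output.

Clustering: K-means with 20 restarts when the domain count is known;
otherwise Louvain on a 15-NN graph of $Z$ at resolution 1.0. Agreement with
ground truth is the adjusted Rand index.

## Synthetic data

The generator mirrors the decoders' generative assumptions so that every
stage is testable without external data: contiguous domains on a regular
lattice (stripes / blocks / Voronoi), ZINB gene counts (gamma-Poisson,
exact for real dispersion), Bernoulli peaks, and NB-mixture proteins with
log-normal background. Marker structure: disjoint marker blocks per domain
group with fold-change 4 over baseline (RNA), accessibility 0.8 vs 0.1
(ATAC), foreground fold 5 (ADT) — strong enough for stable desk-scale
verification, weak enough that noise matters.

The **complementary benchmark** places 4 equal domains on a 2×2 block
layout of a 44×45 lattice (1980 spots): RNA markers differ only between the
top and bottom halves, ADT markers only between left and right. Each
single modality can therefore resolve at most a 2-way split (K-means with
k = 4 on a single modality lands near ARI ≈ 0.5 against the 4-domain
truth), while the fusion can recover all four domains. This operationalizes
the method's central claim in a falsifiable way.

What the simulator does **not** emulate: continuous gradients or
trajectories, batch/slice effects, doublets, segmentation noise, irregular
spot geometries, or realistic gene–gene correlation. Passing these tests
demonstrates the machinery is correct under its own generative
assumptions; it does not certify performance on real tissue.

## Problem sizes and numerical choices

- Verification runs train the benchmark for 30 epochs and the 500-spot
  smoke bundle for 50–100 epochs; the library default remains 300. On the
  benchmark the fused embedding already separates the four domains within
  tens of epochs because the reconstruction gradient dominates early
  training.
- Determinism: one `numpy` `Generator` seeds all initialization; ADT
  sampling uses a spawned child generator; evaluation-mode forward is
  sampling-free. Two identically seeded runs produce bitwise-identical
  embeddings on the same platform.
- Degenerate inputs: all-zero spots pass through preprocessing as zero
  rows (warned); empty peaks and constant features are dropped or mapped
  to zero (warned); duplicate coordinates are legal (kernel weight 1);
  constant-count proteins fall back to a dispersed prior
  $(\bar m, 0.5|\bar m| + 0.1)$ rather than a degenerate GMM fit.
- Ties in K-means / kNN are resolved by the seeded implementations of
  scikit-learn; graph construction breaks distance ties by index order.

## Known limitations

- Attention and the dense spatial-regularizer option are $O(N^2)$; the
  engine is CPU-bound, so very large slides (≫10⁴ spots) are out of
  practical reach without minibatching, which is not implemented.
- Exactly one or two modalities; three-way fusion is not supported.
- The model is transductive: `transform` returns the embedding of the
  fitted spots only; there is no out-of-sample projection.
- 2-D coordinates only; no histology-aware graph construction.
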