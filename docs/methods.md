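# Methods

## Problem and data model

The task is transductive link prediction on a bipartite biological
network: M miRNAs, N diseases, a binary association matrix `G_md` of
experimentally validated links, and one or more square similarity
matrices per node family (functional similarity for miRNAs, semantic
similarity for diseases, both accepted as precomputed inputs; Gaussian
interaction-profile kernels computed from the association matrix).
Similarity matrices are validated to be symmetric within 1e-6 with unit
diagonal and entries in [0, 1]; node ids are sorted lexicographically
so indexing is reproducible.

The GIP kernel uses the standard interaction-profile form
`sim(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` with bandwidth
`γ = n / Σ_i ‖IP(i)‖²` (normalised by the mean squared profile norm);
an all-zero association matrix makes γ undefined and raises. The "ALL"
feature view fuses functional/semantic with GIP by an elementwise mean
(a `prefer_a_nonzero` rule is available, matching the other convention
in this literature).

## Graph construction

* Block adjacency `[[0, G_md],[G_mdᵀ, 0]]`; its symmetric
  renormalisation with self-loops `D^{-1/2}(A+I)D^{-1/2}` feeds the
  transformer's convolution stack. Isolated nodes keep a unit
  self-loop, so normalisation never divides by zero.
* Node features: miRNA row i is `[M_s row i ‖ G_md row i]`, disease
  row j is `[G_md column j ‖ D_s row j]`, width k = M+N. The
  similarity blocks `[M_s; D_s]` alone are dimension-inconsistent, so
  the off-blocks carry the association profiles (a `block_diagonal`
  layout with zero off-blocks is available).
* Attention neighbourhoods: each node keeps its top-k (default 10)
  most-similar same-family partners, ties broken toward the lower
  index, symmetrised by union. The attention encoder reads these
  similarity networks; association structure reaches the model through
  the features and the block adjacency. An option
  (`neighbor_edges="similarity+association"`) also unions association
  edges into the neighbourhoods; we found this invites the encoder to
  memorise training edges by direct lookup (training AUC ≥ 0.9 while
  held-out AUC stalls), so the similarity-network reading is the
  default.
* Hop distances for the Gaussian bias are breadth-first shortest paths
  on the working graph — association edges united with the similarity
  edges — capped at 10 (sentinel for unreachable pairs). On the
  bipartite association graph alone, every same-family pair sits at
  two or more hops, and the bias `−|ω k² + b|` with ω initialised at 1
  would suppress precisely the within-family similarity attention the
  method is premised on; measuring distance on the working graph makes
  similar nodes one hop apart and lets the bias do its intended job of
  favouring close neighbours.

## Encoders, fusion, scoring

GCAN: `gcn_layers` (default 1) GCN propagations with
self-loop-inclusive degrees, then `att_layers` (default 2) multi-head
attention layers (4 heads, head width D/4, LeakyReLU slope 0.2 — the
usual graph-attention convention), concatenated per layer; the final
embedding is the last layer plus learnable scalar multiples of earlier
layers (initialised at 1/(L−1), unconstrained). The aggregation
nonlinearity is ReLU, matching the GCN layer's stated activation.
Attention is computed densely with a neighbourhood mask; every row of
every attention matrix is asserted to sum to 1 within 1e-6 in the
forward pass.

GCT: `conv_layers` (default 2) graph convolutions, one transformer
block: per-head Q/K/V projections, logits `QKᵀ/√d` plus the shared
Gaussian bias (one learnable (ω, b) pair across heads, ω init 1.0,
b init 0.0), softmax, head concatenation through `W_O`, then
`Ã = LN(attn + X)` and `H_TR = LN(FFN(Ã) + Ã)` with a 2×D-wide ReLU
FFN and layer-norm epsilon 1e-5. The bias enters additively inside the
softmax. A single block is used; the residual stream uses the
convolution output.

Gating: depth 2 by default; layer 1 consumes (H_AG, H_TR), later
layers consume (previous output, H_TR); a "parallel" recursion running
a mirrored second stream with swapped operands is available. Dropout
(p = 0.5) applies at every gating layer during training only.

Scoring: pair vector `[h_i ‖ h_{M+j}]` through a 2D→D→1 ReLU MLP with
sigmoid output. Training minimises the mean binary cross-entropy; the
optimiser works on logits (softplus form) for numerical stability,
while the public `bce_loss` clamps probabilities to [1e-7, 1−1e-7].

Ablation variants map onto config switches: DGN-A drops the
transformer's self-attention (convolution stack only), DGN-B drops the
GCN pre-encoding (plain graph attention), DGN-C replaces the gate by
concatenation plus a linear map, DGN-D is a conventional transformer
alone (linear input projection, no graph convolution, no Gaussian
bias, no GCAN, no gating).

## Training protocol

Balanced negative undersampling (all positives plus an equal-size
uniform sample of unobserved pairs, without replacement, seeded), a
stratified 8:2 train/test split, and stratified 5-fold cross-validation
on the training portion; per-fold class balance holds within ±1 by
round-robin dealing with a carried cursor. One balanced negative set is
drawn per run seed.

For every fold, the validation and test positive edges are removed
from the association matrix before the graph, the features and the GIP
kernels are built, so no held-out label leaks through message passing
or through the kernel. Parameters are Xavier-uniform with zero biases,
seeded per fold; Adam with learning rate 1e-3 and weight decay 5e-4;
early stopping on validation AUC with patience 30 within a 300-epoch
budget (package defaults), best-epoch parameters restored.
Classification metrics use threshold 0.5; AUC is rank-based and AUPRC
is the step integral of the precision-recall curve. One root seed
expands into per-component child seeds (sampling, initialisation,
dropout) through a fixed counter scheme, and two runs with identical
configuration and seed produce bit-identical score tables.

"New disease" mode zeroes one disease's association column before
sampling and training, emulating prediction for a disease with no
known links.

## Synthetic benchmark

The generator encodes the method's core premise — that similarity
structure and association structure share a latent cause. Latent
factors U (M×r), V (N×r) have unit-normal entries; pair (i, j) is
positive with probability `sigmoid(s·U_iᵀV_j/√r + c)` with logit scale
s = 3.0 (a unit-variance latent inner product scaled to give a
moderately separable signal, comparable to the discrimination levels
reported on real association benchmarks) and intercept c calibrated by
bisection to the target density; the realised density must land within
10% of target (or four binomial standard deviations on small grids).
Functional/semantic similarity views are cosine similarities of the
latent rows mapped to [0, 1] with clipped Gaussian noise (default sd
0.05), re-symmetrised, unit diagonal. The default benchmark uses
M = 60, N = 40, rank 4, density 0.1, seed 7.

What the benchmark does not emulate: ontology-derived block structure
in semantic similarity, miRNA family structure, the extreme sparsity
and popularity skew of curated databases, and database-versioning
noise. Passing tests on it demonstrates that the pipeline recovers
planted low-rank structure under its own assumptions, not performance
on curated clinical data.

## Scaled-down study sizes

Tests and the acceptance script run the model at embedding dimension
64 with early-stopping patience 60 inside a 600-epoch budget on the
100-node benchmark; the package default (dimension 512, 4 heads, 2
transformer convolutions, 2 gating layers, dropout 0.5) is the
reference configuration for full-size data. Encoder-correctness checks
run at dimension 8 on graphs of at most 6 nodes against naive dense
loop evaluations.

## Known limitations

* On the default benchmark the end-to-end trained model reaches
  held-out AUC around 0.65–0.75 (single split, depending on seed),
  above the logistic-regression-on-raw-profiles baseline but below a
  hand-crafted sharpened similarity-propagation oracle (~0.86). With
  only ~400 balanced training pairs, the concatenation MLP cannot
  reliably learn the multiplicative profile-matching readout that the
  oracle gets for free, and the deep encoders tend toward memorising
  training edges (the motivation for the leakage masking and the
  similarity-only neighbourhoods described above). Larger datasets
  soften both effects.
* Full-graph dense forward passes: memory grows as (M+N)²; the
  implementation targets graphs up to a few thousand nodes.
* Transductive only: scoring a miRNA or disease absent from the graph
  requires rebuilding and retraining (see "new disease" mode).
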