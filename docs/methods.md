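# Methods

## Problem and model

`scdgc` performs supervised cell-type classification from scRNA-seq data.
Its inputs are a cells × genes expression matrix X ∈ ℝ^{N×M}, a per-cell
type label, and a weighted gene–gene interaction table (STRING-style
probabilities in [0, 1]). The central idea is to let a graph convolutional
network propagate each cell's expression profile over the gene interaction
graph, so that a gene's representation is informed by the expression of
its interaction partners, while a parallel fully connected branch captures
global, graph-independent structure.

### Preprocessing

1. Cells labeled `unlabeled`, `debris` or `doublet` (case-insensitive,
   configurable) are removed.
2. Genes whose counts summed over all cells are below 5 are removed. The
   alternative stricter reading — per-cell maximum below 5 — is available
   as `gene_filter_mode="max"`; the total-count rule is the default
   because the intent of the filter is to drop genes that are rarely
   expressed overall. The filter is idempotent.
3. Counts are mapped to `log2(1 + x)`. Base 2 with a pseudocount of 1 is
   the dominant scRNA-seq convention and maps zero counts to exactly zero.
   No library-size normalization is applied by default.
4. Genes are ranked by sample variance of the log counts (default) or by
   the one-way ANOVA F statistic across cell types (`method="anova_f"`,
   computed by `sklearn.feature_selection.f_classif`), ties broken by gene
   id for determinism, and the top k = 1000 are kept. The selector records
   the cells it was fitted on; in the training pipeline it is fitted on
   the training split and merely *applied* to validation/test data, which
   prevents selection leakage. Constant genes score 0 under both methods.

### Gene graph

The adjacency A (M × M over the selected genes) is symmetric with zero
diagonal: self-interaction of a gene carries no information. Edges whose
genes fall outside the selected set are skipped; duplicate unordered pairs
keep their maximum weight. Every convolution uses the first-order
propagation matrix

    P = D̂^{-1/2} (A + I) D̂^{-1/2},   D̂ = diag(rowsums(A + I)).

Adding the identity *before* computing degrees guarantees strictly
positive degrees, so isolated genes are well defined (P[i,i] = 1). P is
symmetric, non-negative, and its spectral radius is at most 1, so deep
stacks of convolutions cannot blow up the feature scale. P is stored
dense; at the package's design scale (M ≤ ~1000) this is a few megabytes.

### Network

With K = 4 convolution layers and c = 5 channels:

* **Channel lift** — H₀[b,m,:] = X[b,m]·w + b, a learned 1×1 projection
  from one input channel to c channels. The "kernel size" of a
  first-order spectral convolution has no spatial width; the free width
  is the channel (output-column) dimension of W, which is where the value
  5 enters.
* **Dense connectivity** — layer k receives the attention-weighted sum of
  *all* previous representations Σ_{u<k} β_u H_u and applies
  H_k = ReLU(P · H_in · W_k + b_k). The per-layer softmax weights come
  from a scorer s_u = w₂ · ReLU(W₁ v_u), where v_u is the mean over batch
  and genes of H_u's channel vector. Pooling before scoring keeps the
  scorer's parameter shapes independent of batch size, gene count and
  layer count; each connection site has its own scorer parameters.
* **Aggregation** — a final scorer of the same form weights H₀..H_K into
  Hout = ReLU(Σ_u α_u H_u). This counteracts over-smoothing: the model
  can emphasize shallow layers when deep ones become too diffuse.
* **Graph head** — max-pooling over the channel axis (B × M), then a
  dense layer + ReLU to a 32-dimensional embedding. Pooling over channels
  rather than genes preserves per-gene resolution for the projection.
* **FNN branch** — dense M→256 + ReLU, dense 256→32 + ReLU on the raw
  log-expression input.
* **Decoder** — the flattened Hout through two dense layers
  (M·c → 256 → M, ReLU in the middle, linear output) reconstructs the
  input expression; its mean squared error is the auxiliary
  feature-reconstruction loss that anchors the encoder to the data.
* **Head** — the two 32-d embeddings are concatenated and mapped by a
  single dense layer + softmax to class probabilities. Concatenation +
  linear head is the simplest fusion that lets either branch dominate.

ReLU is the activation everywhere in hidden layers; softmax appears only
in the attention weights and the classifier head. Parameters are
Xavier-uniform initialized from a seeded generator, biases zero. The
`NoDC` ablation (no dense connectivity) makes each layer read only its
predecessor and uses H_K directly as Hout; it allocates no attention
parameters at all, so ablations are pure configuration states.

### Losses and training

    L = L_FNN + λ₁ L_FR + λ₂ L_VAT,   λ₁ = 1, λ₂ = 0.1

* L_FNN — cross-entropy of the softmax output (log probabilities floored
  at 1e-12).
* L_FR — elementwise mean squared error of the reconstruction.
* L_VAT — virtual adversarial smoothness: the mean KL divergence between
  the clean predictive distribution (treated as a constant target) and
  the prediction at x + λ_lds·r_vat. The perturbation r_vat is found by
  power iteration: start from a unit-normalized Gaussian direction,
  differentiate KL(p(x) ‖ p(x + ξ r)) with respect to r, re-normalize,
  repeat `ip` times, then scale to ‖r_vat‖₂ = ε per cell. Defaults
  ε = 1.0, ξ = 1e-6, ip = 1, λ_lds = 1.0. Cells where the KL gradient
  vanishes (locally flat model) receive a zero perturbation.

Batch reductions are means rather than sums so that the λ weights do not
depend on the batch size; `loss_reduction="sum"` restores plain sums.

Optimization is plain SGD: learning rate 0.01 with step decay ×0.5 every
30 epochs, weight decay 5e-4 on weights (not biases), batch size 128,
100 epochs, validation metrics logged every 10 epochs. The split is
stratified 80/10/10 with largest-remainder rounding per class; classes
with fewer than 3 cells go entirely to training with a warning. VAT is
active from the first epoch. All randomness (init, shuffling, VAT draws)
flows from explicit seeds, so a run is reproducible bit-for-bit.

The network and its gradients run on a small reverse-mode automatic
differentiation engine over float64 NumPy arrays (`scdgc._autodiff`),
written for exactly the operations this architecture needs and verified
against central finite differences in the test suite.

## Evaluation

Accuracy, macro-averaged precision/recall/F1 (weighted averaging
available), the confusion matrix, per-class one-vs-rest ROC AUC with its
unweighted mean, and a "binarized" micro AUC over all flattened
(cell, class) indicator/score pairs. Macro averaging is the default
because it is the stricter convention for imbalanced cell-type
distributions. Note the micro AUC is a genuinely different statistic from
the per-class AUCs (cross-class score pairs enter it), even for two
complementary classes.

## Synthetic data

The generator draws cells from `n_types` types and partitions genes into
contiguous co-expression modules; type t elevates the log-mean of its
marker module by `mean_shift`. Counts are negative-binomial with
variance μ + μ²/dispersion (baseline mean 1.0, dispersion 2.0), then
zero-inflated at `dropout_rate`. The interaction graph mirrors the block
structure (within-module weight 0.8, between-module 0.1 by default), so
graph propagation genuinely carries class signal. Designated "rare"
genes are overwritten with counts summing to a value drawn from {0..4},
which makes the gene-filter tests exact rather than probabilistic;
designated invalid cells are labeled `unlabeled`/`debris`/`doublet` in
rotation.

The default condition — 600 cells, 120 genes, 4 balanced types,
mean_shift 2.5, dropout 0.2 — is the study condition used by the test
suite and the acceptance script, with top-100 gene selection and the
training defaults above. Robustness comparisons add Gaussian noise
(σ = 0.5 on the log scale) to test inputs at evaluation time.

What the generator does *not* emulate: batch effects, library-size
variation, doublet expression mixtures, gene-length or capture biases,
and realistic correlation structure beyond the block model. Passing the
end-to-end tests therefore demonstrates that the implementation learns
and generalizes on data whose structure matches its assumptions — not
that it reaches any particular accuracy on real tissues.

## Numerical choices and degenerate inputs

* float64 throughout; log probabilities floored at 1e-12.
* Ranking ties (gene selection, arg-max pooling) break deterministically:
  lexicographic gene id, first index respectively.
* Zero-gradient VAT rows return zero perturbations instead of NaNs.
* An all-invalid cell table, a negative filter threshold, non-symmetric
  or negative adjacencies, weights outside [0, 1], duplicate ids, and
  0-based MatrixMarket indices are all rejected with named errors.
* Checkpoints are a directory of `.npy` arrays plus a JSON manifest;
  save → load → forward is bit-identical, and the files are byte-stable
  across runs (no embedded timestamps).

## Known limitations

* Mini-batch SGD is single-threaded NumPy; the design scale is thousands
  of cells and ~1000 genes, not atlas-scale data.
* The attention scorer pools over the batch, so attention weights are
  batch-level rather than per-cell (per-cell outputs remain independent:
  scores only weight shared layer representations; with a fixed
  parameter set the weights are deterministic functions of the batch).
  Evaluation uses full-batch forward passes, making reports independent
  of batch partitioning.
* ANOVA-based selection uses labels and is therefore fitted on the
  training split only; variance selection is label-free.
* The micro ("binarized") AUC mixes scores across classes and should be
  compared across models, not interpreted as a per-class ranking quality.
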