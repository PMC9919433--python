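# scdgc — adversarially trained dense graph convolutional networks for single-cell classification

`scdgc` assigns cell types to single cells from scRNA-seq expression
profiles, using the interactions between genes as an explicit inductive
bias. It is aimed at computational biologists who have (a) a cells ×
genes count matrix, (b) a per-cell type label for training, and (c) a
weighted gene–gene interaction table (e.g. STRING combined scores).

## The model

After filtering (invalid cells; genes with total counts < 5),
`log2(1+x)` scaling and top-k variance/ANOVA gene selection, expression
profiles are classified by a hybrid network over the gene graph:

* **Graph branch** — K = 4 first-order spectral graph convolutions
  `H_k = ReLU(P·H·W_k + b_k)` with `P = D̂^{-1/2}(A+I)D̂^{-1/2}`, the
  symmetric-normalized gene adjacency with self-loops. Layers are
  *densely connected*: each layer consumes a softmax-attention-weighted
  sum of all previous representations, and a final attention step
  aggregates every layer into one representation, counteracting
  over-smoothing.
* **Fully connected branch** — M→256→32 dense layers capture global,
  graph-free structure.
* The two 32-d embeddings are concatenated into a softmax classifier; a
  two-layer decoder reconstructs the input expression from the aggregated
  graph representation.

Training minimizes

    L = L_FNN + λ₁·L_FR + λ₂·L_VAT       (λ₁ = 1, λ₂ = 0.1)

where `L_FNN` is the classification cross-entropy, `L_FR` the
reconstruction MSE, and `L_VAT` the *virtual adversarial training*
penalty `KL(p(y|x) ‖ p(y|x + r_vat))` with `r_vat` the worst-case
perturbation of norm ε found by power iteration — a smoothness
regularizer that improves robustness to input noise. Optimization is
seeded SGD (lr 0.01, step decay, weight decay 5e-4, batch 128, 100
epochs) on a stratified 80/10/10 split. The NoVAT / NoDC / NoFR
ablations are pure configuration states.

The network and its gradients run on a small reverse-mode autodiff
engine over NumPy float64 (`scdgc._autodiff`), finite-difference-checked
in the test suite. See `docs/methods.md` for the full model description
and design rationale.

## Worked example

A bundled generator produces cell-type-structured counts together with a
consistent gene-interaction graph, so the whole pipeline runs offline:

```bash
cat > spec.yaml <<EOF
synthetic:
  n_cells: 300
  n_genes: 60
  n_types: 3
  n_modules: 3
EOF
cat > train.yaml <<EOF
train:
  epochs: 40
EOF

scdgc simulate   --config spec.yaml --out-dir sim --seed 7
scdgc preprocess --expr sim/expression.tsv --labels sim/labels.tsv \
                 --top-k 50 --out prep
scdgc build-graph --interactions sim/interactions.tsv \
                  --genes prep/selector.tsv --out graph
scdgc train      --expr prep/expression.selected.tsv --labels prep/labels.tsv \
                 --graph graph --config train.yaml --seed 7 --out run
scdgc evaluate   --ckpt run/checkpoint --expr prep/expression.selected.tsv \
                 --labels prep/labels.tsv --graph graph \
                 --cells run/test_cells.tsv --out report.json
```

The final command prints

```
accuracy=1.0000 f1=1.0000 mean_auc=1.0000 binary_auc=1.0000
```

meaning every held-out test cell of the three well-separated synthetic
types was assigned its true type, with perfect one-vs-rest ranking
(AUC 1.0 in both the per-class-mean and the binarized micro sense).
`run/history.tsv` logs the per-epoch loss components (`l_fnn`, `l_fr`,
`l_vat`, `total`) and validation accuracy every 10 epochs; `report.json`
holds the metrics plus the confusion matrix, and `*.confusion.tsv` a
readable copy. Re-running with the same seed reproduces every output
byte for byte.

Programmatic use mirrors the CLI: `scdgc.generate_dataset`,
`scdgc.preprocess_pipeline`, `scdgc.build_adjacency`, `scdgc.train`,
`scdgc.evaluate_predictions`.

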