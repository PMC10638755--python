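# scattrib

Neural-network attribution methods for marker gene selection from
single-cell RNA-seq data, with dataset-sampling designs and an evaluation
harness — a reusable, tested toolkit for benchmarking deep-learning-based
feature selection against traditional differential-distribution approaches.

## The problem

Selecting informative genes is a core step in scRNA-seq analysis: most of
the thousands of measured genes carry no signal for tasks such as cell-type
classification or marker identification. The classical approach tests each
gene separately for differential distribution between one cell type and the
rest (e.g. a Wilcoxon rank-sum test). An alternative is *embedded* feature
selection: train a neural-network cell-type classifier on all genes at once
and extract per-gene importance from the trained model, so that panels of
jointly informative, non-redundant genes are selected for all cell types
simultaneously.

## What the package implements

**Classifier.** A fixed multilayer perceptron `genes → 1024 → 512 → types`
with LeakyReLU and ReLU hidden activations, softmax cross-entropy training
(batch 64, 20 epochs, Adam 1e-3), implemented directly on NumPy arrays so
every attribution algorithm has access to the per-layer weights and
activations.

**Six attribution methods** mapping (model, cell `x`, target type `c`) to a
score per gene, all explaining the pre-softmax logit `t = f_c(x)`:

- *LayerRelProp* — layer-wise relevance propagation with the
  ε-stabilized z-rule; the relevance sum is conserved per layer,
  `f(x) = Σᵢ Rᵢˡ` for every layer `l` (up to ε and bias leakage).
- *DeepLIFT* (rescale rule) — multipliers `m = Δout/Δin` chained through
  the layers against an all-zero reference; satisfies summation-to-delta
  `Σᵢ R_{Δxᵢ Δt} = Δt` exactly.
- *GradientShap* — expected gradients: `k = 5` Gaussian-noise draws per
  cell, a random baseline, a uniform path position α, scores
  `∂t/∂x|_(x₀+α(x̃−x₀)) · (x̃ − x₀)` averaged over draws.
- *Occlusion* — slide a window of 3 genes set to baseline 0, record the
  logit drop per placement, average the drops covering each gene.
- *FeatureAblation* — logit drop from zeroing each gene independently.
- *LIME* — 500 random binary gene masks, ridge-regularized linear
  surrogate from masks to logits; coefficients are the scores.

On a bias-free linear model all six collapse to `scoreᵢ = w_{i,c} · xᵢ`
(exactly, or in expectation for the Monte-Carlo methods) — a cross-method
identity the test suite enforces.

**Workflow.** Per cell type `c`: attribute every cell of type `c` with
target `c`, sum the per-cell scores into a cumulative importance per gene,
rank descending (ties broken lexicographically). Gene sets for evaluation
are the union of each type's top-k (k ∈ {5, 10, 20}).

**Sampling designs.** Dataset grids over a (real or synthetic) atlas:
varying cell-type counts (5–20, 200 cells each), cells per type (50–250 at
10 or 20 types), and major:minor imbalance (2:1, 4:1, 10:1) — 80, 200 and
120 datasets respectively at 10 repetitions × 2 atlases — plus a
reproducibility series that fixes the cell types and re-samples only cells.

**Evaluation.** Stratified 50/50 split; KNN (k = 7) and RBF-SVM classifiers
on the selected genes; one-vs-all confusion counts per type with
`F1 = 2TP/(2TP+FP+FN)`, `sensitivity = TP/(TP+FN)`,
`specificity = TN/(TN+FP)` and unweighted macro averages; OLS slopes of F1
against a design setting; pairwise Pearson correlation of per-gene
statistics across repetitions; top-k Jaccard overlap between rankings;
pseudo-bulk condition classification under 5-fold CV.

**Synthetic data.** A seeded negative-binomial generator
(variance `μ + μ²/θ`) with library-size variation, planted per-type marker
genes at a configurable log2 effect size, and an exact truth table — every
capability is testable without downloads.

## Worked example

```sh
python examples/04_rank_and_evaluate.py
```

```
 DeepLIFT: planted markers in each type's top-10 [9, 10, 9, 10, 9]; union of 50 genes -> macro-F1 0.977 (sens 0.977, spec 0.994)
 Wilcoxon: planted markers in each type's top-10 [10, 10, 10, 10, 10]; union of 50 genes -> macro-F1 0.990 (sens 0.990, spec 0.997)
```

Five synthetic cell types with ten planted markers each: both the
DeepLIFT-based ranking (trained classifier + attribution aggregation) and
the Wilcoxon baseline place nearly all planted markers in their type's
top-10, and a KNN classifier restricted to the selected 50-gene union
separates the held-out cells almost perfectly. The other scripts in
`examples/` walk through simulation/normalization, the sampling designs,
the six attribution methods and their identities, and reproducibility
metrics.

A thin CLI mirrors the library: `scattrib simulate | sample | rank |
evaluate | benchmark | time` (see `scattrib --help`).

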