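# Methods

This note records the models, conventions and design choices behind
`scattrib`, in the spirit of the methods documentation of packages such as
statsmodels or scanpy: what is computed, under which assumptions, and which
decisions were genuinely open.

## Classifier

The classifier is a three-layer perceptron: input dimension = number of
genes, hidden layers of 1024 and 512 units with LeakyReLU (negative slope
0.01) and ReLU activations respectively, output dimension = number of cell
types. Softmax is applied only at loss/prediction time; all attribution is
performed on the pre-softmax logit of the target class, because the
conservation identities of relevance propagation and DeepLIFT are stated
for the network score and the softmax would couple the classes. For
relevance propagation the model is built in `lrp_mode`, which replaces
LeakyReLU by ReLU (the z-rule treatment of ReLU relevance is standard;
LeakyReLU is not supported there).

Training is minibatch cross-entropy with batch size 64 for 20 epochs.
The optimizer, learning rate and initialization are deliberate choices, not
derived quantities: Adam at 1e-3 (the standard default at this architecture
scale), Kaiming-uniform initialization (`U(±√(6/fan_in))`, zero biases),
both seeded. There is no early stopping, dropout or batch-norm. Class
encoding is the sorted order of the cell-type labels; this canonical order
is shared between training and attribution targets so rankings cannot
depend on cell order in the matrix.

The network, backpropagation and Adam are implemented directly on NumPy
arrays. Every attribution algorithm needs per-layer weights,
pre-activations and post-activations, so the forward pass returns a full
`ForwardTrace`; a transparent array implementation keeps those contracts
trivially inspectable and the whole package dependency-light.

## Attribution methods

All six methods return one score per gene per cell for a chosen target
class. Gradient-based methods are batched over cells; perturbation-based
methods evaluate masked inputs one at a time so that their outputs are
bit-identical to a naive loop (this makes the ablation/occlusion identity
`Occlusion(window=1) ≡ FeatureAblation` exact, not approximate, at the cost
of speed — consistent with perturbation methods being the slow family).

- **LayerRelProp.** ε-stabilized z-rule, ε = 1e-9. The message from neuron
  k to its input i is `aᵢ w_{ik} / (z_k + ε·sign(z_k)) · R_k`; ReLU layers
  pass relevance through unchanged. Bias relevance is absorbed rather than
  redistributed, so with nonzero biases part of the relevance leaks; on
  zero-bias networks conservation holds to about 1e-3 relative (governed by
  ε). The rule variant is swappable in principle; only the z-rule ships.
- **DeepLIFT (rescale rule).** Reference input is the all-zero vector —
  the natural "absence of expression" point of log-normalized data —
  configurable. Nonlinearity multipliers are secant slopes Δa/Δz with a
  gradient fallback when |Δz| < 1e-7; linear layers chain multipliers
  through their weights; scores are `m · Δx`. Summation-to-delta holds to
  machine precision (tested at 1e-6 relative).
- **GradientShap.** k = 5 noise draws of N(0, 1) per cell, path position
  α ~ U(0,1), gradient evaluated at `x₀ + α(x̃ − x₀)`. The formula's
  denominator is read as "the gradient with respect to the input, evaluated
  at the path point" (the standard expected-gradients reading); the literal
  `∂t/∂(α(x̃−x₀))` form is ambiguous and not used. The baseline is all-zero
  by default; a "mixed" mode draws a random cell from a supplied pool with
  probability 1/2 (else zeros). The linear-model oracle pins only the
  zero-baseline mode.
- **Occlusion.** Window of 3 contiguous genes (stride 1) set to baseline 0;
  a gene's score is the mean logit drop over the placements covering it,
  edge genes averaging over their fewer available placements. The gene
  order is whatever the matrix carries; contiguity has no biological
  meaning here, which is inherent to applying an image-domain method to
  expression vectors.
- **FeatureAblation.** Per-gene logit drop against baseline 0; genes
  already at baseline score exactly zero (and are skipped, which makes
  sparse expression vectors cheap).
- **LIME.** 500 binary masks keeping each gene with probability 1/2,
  masked genes set to 0, ridge-regularized (λ = 1e-3) linear surrogate with
  uniform sample weights fit from masks to target logits. No locality
  kernel: uniform weighting is reproducible and dialect-free, which we
  prefer over fidelity to any one LIME implementation. Masking acts on the
  normalized values the model consumes, not on counts. The ridge penalty
  shrinks coefficients by a deterministic ~λ-scale relative amount; the
  surrogate-limit tests budget for this explicitly.

Cross-method identity: on a bias-free single linear layer every method
reduces to `w_{i,target} · xᵢ` — exactly for the deterministic methods, in
expectation for GradientShap and LIME. This is the strongest shared oracle
and is enforced in the acceptance tests.

## Ranking

For each cell type, attributions are computed for the cells of that type
only and summed per gene (cells of other types do not enter that type's
score, so they are skipped for cost; the aggregation is a sum, hence
order-invariant, and cells are processed in a canonical id-sorted order so
the invariance is exact in floating point). Genes are ranked by descending
cumulative score with lexicographic gene-id tie-breaks, recorded on the
ranking object. Negative cumulative scores rank below positive ones; sign
handling is otherwise not interpreted.

The Wilcoxon baseline ranks genes per cell type by a one-vs-rest rank-sum
z statistic: midranks for ties, tie-corrected variance
`n₁n₂/12 · ((N+1) − Σ(t³−t)/(N(N−1)))`, continuity correction of 1/2 toward
the mean, zero-variance guarded to z = 0; genes are ordered upregulated
first by signed z. One-sided p-values use direction-specific continuity
corrections. On tiny tie-free groups (3 vs 3) the normal approximation
stays within 0.02 of the exact permutation p; heavy ties at such sizes can
push it further, which is a property of the approximation, not of the
implementation. A generic `-log10(p) · sign(log2FC)` transform is provided
to rank external tools' p-value tables consistently; those tools themselves
(DESeq2, limma, scDD, RelieF, random forests) are not reimplemented.

## Sampling designs

Three grids (cell-type count 5/10/15/20 at 200 cells; cells per type
50–250 at 10 or 20 types; imbalance 2:1/4:1/10:1 with half the types major
at 200 cells) × 10 repetitions × 2 atlases enumerate 80, 200 and 120
datasets. Types are re-drawn each repetition; in imbalance designs the
first half of the randomly ordered selected types are major (the assignment
is otherwise arbitrary). Per-dataset seeds are derived from a single base
seed via `SeedSequence(base, design, setting, repetition)` so any dataset
is reconstructible in isolation. The 1% low-expression gene filter is
applied per sampled dataset after normalization for the three main designs
and skipped for the reproducibility series, whose datasets must share the
full gene axis. Normalization happens per dataset after sampling.

Preprocessing of an atlas applies, in order: drop all-zero cells, drop
all-zero genes, drop cell types with fewer than 300 cells (strict), then
re-check for genes emptied by the type removal — so the "no all-zero gene"
invariant survives and the operation is idempotent. "LogNormCount"
normalization is implemented as library-size size factors scaled to mean 1
followed by log2(x/sf + 1), the cited implementation's default dialect.
Counts must be integers; real-valued input is rejected, never rounded.

## Evaluation

One-vs-all confusion counts are derived from multiclass predictions
(TP = correctly predicted members of the class, etc.; the four counts
partition the test set for every class). Macro metrics are unweighted means
over classes. KNN uses k = 7 with Euclidean distance on the selected-gene
log-normalized submatrix and no further scaling; the SVM uses an RBF kernel
with library-default regularization (both recorded in the report and
configurable). The train/test split is stratified 50/50; odd type sizes
put the extra cell in the test half. Reproducibility correlations are
computed on the importance statistics by default with a rank-transform
flag; constant vectors make r undefined and such pairs are excluded with a
NaN marker. Pseudo-bulk profiles average cells within (sample, condition)
groups when sample ids exist, otherwise cells of each condition are
randomly partitioned into ≥5 pseudo-replicates so 5-fold CV is defined.
Slope coefficients are fit by OLS to mean F1 per setting (a per-repetition
fit is a caller choice — pass the raw pairs).

## Synthetic data

The generator emulates what the benchmark needs from atlas-derived data:
discrete cell types, overdispersed counts, library-size variation, a small
planted marker set and a large uninformative majority. Counts are
gamma-Poisson: gene-by-type mean μ, dispersion θ (variance μ + μ²/θ;
θ = 2 by default, moderate Smart-seq2-like overdispersion), per-cell
library factors LogNormal with sd 0.3 normalized to mean 1. Baseline gene
means are LogNormal(ln 0.5, 1); genes chosen as markers draw their baseline
from LogNormal(0, 0.5) instead, so planted markers are moderately expressed
genes — as real marker genes are — rather than near-silent ones, and their
mean is multiplied by `2^effect` (default effect 2) in their own type only.
Marker sets are disjoint across types and recorded exactly in a truth
table. An optional condition axis (two labels assigned independently of
cell type, a configurable set of non-marker genes boosted in one condition)
supports the pseudo-bulk tests. Defaults — 2000 genes, 10 types × 200
cells, 10 markers per type — mirror the mid-sized benchmark datasets.

What the generator does *not* model: zero-inflation beyond NB sampling,
batch or donor effects, gene-gene correlation beyond the type structure,
ambient RNA. Passing tests on this data therefore demonstrate algorithmic
correctness and signal recovery under clean conditions, not robustness to
every artifact of real scRNA-seq data.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by choice: toy networks
(≈10 inputs, two hidden layers) for the algebraic identities, where the
identities are scale-free; a 2000-gene × 2000-cell dataset with the default
architecture for end-to-end marker recovery. Tolerances: DeepLIFT
summation-to-delta 1e-6 relative (exact rule), relevance conservation 1e-3
relative on zero-bias networks (ε leakage), Monte-Carlo comparisons within
3 standard errors over 200 seeded draws (plus the documented ridge
allowance for LIME), Wilcoxon-vs-exact p within 0.02. Degenerate inputs —
all-zero cells, single-expressed-gene cells, constant genes, constant
statistic vectors — are covered by explicit guards rather than left to
floating-point accident.

## Known limitations

- Attribution of cells *outside* the target type is supported by the API
  but not used by the ranking aggregation (the type-restricted sum is the
  documented behavior).
- The timing harness reports wall-clock only and asserts nothing: absolute
  times are hardware-bound.
- Preprocessing reproduces the published atlas-filtering rules, but
  verifying the resulting atlas dimensions requires downloading the
  multi-gigabyte source matrices and is outside the test suite.
- Occlusion's gene windows follow matrix order; with no natural gene
  adjacency the window size acts mainly as a smoothing parameter.
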