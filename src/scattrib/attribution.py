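"""Six attribution algorithms scoring genes for a trained classifier.

Each method maps (model, cell expression vectors, target class) to one
importance score per gene per cell.  Three are gradient-based —
layer-wise relevance propagation (``layer_relprop``), DeepLIFT with the
rescale rule (``deeplift``), and GradientShap (``gradient_shap``) — and
three perturbation-based — ``occlusion``, ``feature_ablation`` and
``lime``.  All methods explain the pre-softmax logit of the target class:
the relevance-conservation and summation-to-delta identities hold for the
network score, and the softmax would couple the classes.

Contracts worth knowing:

- DeepLIFT satisfies summation-to-delta exactly: the per-gene scores sum
  to ``t - t0``, the logit difference between the input and the reference.
- LRP uses the epsilon-stabilized z-rule (epsilon 1e-9) and conserves the
  per-layer relevance sum up to the epsilon leakage and the bias mass
  (bias relevance is absorbed, not redistributed).
- Occlusion with window 1 is definitionally identical to feature ablation.
- On a bias-free single linear layer every method reduces to
  ``score_i = w_{i,target} * x_i`` (exactly, or in expectation for the
  Monte-Carlo methods).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import gzip
import json
import os

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .mlp import MLPModel, forward, input_gradient, _act, _as_batch

METHODS = (
    "LayerRelProp", "DeepLIFT", "GradientShap", "Occlusion",
    "FeatureAblation", "LIME",
)
GRADIENT_METHODS = ("LayerRelProp", "DeepLIFT", "GradientShap")
PERTURBATION_METHODS = ("Occlusion", "FeatureAblation", "LIME")

LRP_EPS = 1e-9
DEEPLIFT_DELTA_EPS = 1e-7


@dataclass
class AttributionConfig:
    """Method hyperparameters; defaults follow the benchmark protocol."""

    occlusion_window: int = 3
    baseline_value: float = 0.0
    gradshap_k: int = 5
    gradshap_noise_sd: float = 1.0
    gradshap_baseline: str = "zeros"   # "zeros" or "mixed" (random cell / zeros)
    baseline_pool: np.ndarray | None = None  # candidate baselines for "mixed"
    lime_n_samples: int = 500
    lime_ridge: float = 1e-3
    deeplift_reference: np.ndarray | None = None  # default all-zero
    seed: int = 0

    def validate_occlusion(self, n_genes: int) -> None:
        if self.occlusion_window < 1:
            raise ValueError("occlusion window must be >= 1")
        if self.occlusion_window > n_genes:
            raise ValueError("occlusion window exceeds the gene dimension")

    def validate_gradshap(self) -> None:
        if self.gradshap_k < 1:
            raise ValueError("gradshap needs k >= 1")

    def validate_lime(self) -> None:
        if self.lime_n_samples < 2:
            raise ValueError("lime needs at least two sampled points")


@dataclass
class AttributionMatrix:
    """Per-cell, per-gene scores for one method and one target class."""

    scores: np.ndarray          # (n_cells, n_genes)
    method: str
    target_class: object
    config: AttributionConfig

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution produced non-finite scores")

    def save(self, prefix: str, gene_ids=None, model_checksum: str = "") -> None:
        """Write scores as gzipped TSV plus a JSON sidecar."""
        os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
        cols = list(gene_ids) if gene_ids is not None else [
            f"g{i}" for i in range(self.scores.shape[1])
        ]
        with gzip.open(prefix + ".tsv.gz", "wt") as fh:
            pd.DataFrame(self.scores, columns=cols).to_csv(fh, sep="\t", index=False)
        cfg = {k: v for k, v in asdict(self.config).items()
               if not isinstance(v, np.ndarray) and v is not None}
        with open(prefix + ".json", "w") as fh:
            json.dump({"method": self.method, "target_class": str(self.target_class),
                       "config": cfg, "model_checksum": model_checksum}, fh, indent=1)


# ---------------------------------------------------------------------------
# Gradient-based methods
# ---------------------------------------------------------------------------

def layer_relprop(
    model: MLPModel, x: np.ndarray, target: int,
    config: AttributionConfig | None = None, *, strict: bool = True,
) -> np.ndarray:
    """Layer-wise relevance propagation with the epsilon-stabilized z-rule.

    Relevance starts at the target logit and is propagated backwards; the
    message from neuron k of a layer to its input i is
    ``a_i w_ik / (z_k + eps * sign(z_k)) * R_k``.  Requires a ReLU-only
    network in strict mode (relevance passes unchanged through ReLU).
    """
    if strict and not model.is_relu_only():
        raise ValueError("layer_relprop requires an lrp_mode (ReLU-only) model")
    X = _as_batch(x, model.n_inputs)
    tr = forward(model, X)
    R = np.zeros_like(tr.logits)
    R[:, target] = tr.logits[:, target]
    n_layers = len(model.layers)
    for i in range(n_layers - 1, -1, -1):
        a_prev = tr.post_activations[i - 1] if i > 0 else tr.x
        z = tr.pre_activations[i]
        denom = z + LRP_EPS * np.where(z >= 0, 1.0, -1.0)
        R = a_prev * ((R / denom) @ model.layers[i].W.T)
    return R if np.asarray(x).ndim == 2 else R[0]


def deeplift(
    model: MLPModel, x: np.ndarray, target: int,
    config: AttributionConfig | None = None,
) -> np.ndarray:
    """DeepLIFT rescale rule against a reference input (default all-zero).

    A nonlinearity's multiplier is the secant slope ``delta_out/delta_in``
    (gradient fallback when ``|delta_in| < 1e-7``); linear layers chain the
    multiplier through their weights.  Scores are ``m * (x - x0)`` and sum
    exactly to the logit difference ``t - t0`` (summation-to-delta).
    """
    config = config or AttributionConfig()
    X = _as_batch(x, model.n_inputs)
    ref = config.deeplift_reference
    ref = np.zeros(model.n_inputs) if ref is None else np.asarray(ref, dtype=float)
    if ref.shape != (model.n_inputs,):
        raise ValueError("reference length must match the gene dimension")
    tr = forward(model, X)
    tr0 = forward(model, ref)
    m = np.zeros_like(tr.logits)
    m[:, target] = 1.0
    n_layers = len(model.layers)
    for i in range(n_layers - 1, -1, -1):
        if i < n_layers - 1:
            dz = tr.pre_activations[i] - tr0.pre_activations[i]
            da = tr.post_activations[i] - tr0.post_activations[i]
            kind = model.activations[i]
            slope_at = np.where(tr.pre_activations[i] > 0, 1.0,
                                0.0 if kind == "relu" else 0.01)
            ratio = np.where(np.abs(dz) < DEEPLIFT_DELTA_EPS, slope_at,
                             da / np.where(np.abs(dz) < DEEPLIFT_DELTA_EPS, 1.0, dz))
            m = m * ratio
        m = m @ model.layers[i].W.T
    scores = m * (X - ref[np.newaxis, :])
    return scores if np.asarray(x).ndim == 2 else scores[0]


def gradient_shap(
    model: MLPModel, x: np.ndarray, target: int,
    config: AttributionConfig | None = None,
) -> np.ndarray:
    """Expected-gradients style scores with Gaussian input noise.

    For each cell and each of ``k`` draws: perturb the input with N(0, sd)
    noise, draw a baseline (all-zero, or with probability 1/2 a random cell
    from ``baseline_pool`` in "mixed" mode), draw a path position
    ``alpha ~ U(0,1)``, take the gradient of the target logit at
    ``x0 + alpha * (x_noisy - x0)`` and accumulate
    ``grad * (x_noisy - x0)``.  The per-cell score is the mean over draws.
    """
    config = config or AttributionConfig()
    config.validate_gradshap()
    X = _as_batch(x, model.n_inputs)
    rng = np.random.default_rng(config.seed)
    n, d = X.shape
    acc = np.zeros_like(X)
    for _ in range(config.gradshap_k):
        noisy = X + rng.normal(0.0, config.gradshap_noise_sd, size=X.shape)
        if config.gradshap_baseline == "zeros" or config.baseline_pool is None:
            base = np.zeros_like(X)
        elif config.gradshap_baseline == "mixed":
            pool = np.asarray(config.baseline_pool, dtype=float)
            pick = rng.integers(0, pool.shape[0], size=n)
            use_pool = rng.random(n) < 0.5
            base = np.where(use_pool[:, None], pool[pick], 0.0)
        else:
            raise ValueError(f"unknown baseline mode {config.gradshap_baseline!r}")
        alpha = rng.uniform(0.0, 1.0, size=(n, 1))
        point = base + alpha * (noisy - base)
        grad = input_gradient(model, point, target)
        acc += grad * (noisy - base)
    scores = acc / config.gradshap_k
    return scores if np.asarray(x).ndim == 2 else scores[0]


# ---------------------------------------------------------------------------
# Perturbation-based methods
# ---------------------------------------------------------------------------

def _masked_drops(
    model: MLPModel, xv: np.ndarray, target: int, masks: np.ndarray, base: float,
) -> np.ndarray:
    """Logit drops ``f(x) - f(x with masked genes at baseline)`` per mask row.

    A mask row that changes nothing is skipped (its drop is exactly 0), so
    sparse expression vectors are cheap under a zero baseline.  Masked
    inputs are evaluated one at a time so scores are bit-identical to a
    plain loop over single forward passes.
    """
    f_full = forward(model, xv).logits[0, target]
    drops = np.zeros(masks.shape[0])
    changes = masks & (xv != base)[np.newaxis, :]
    for p in np.flatnonzero(changes.any(axis=1)):
        xm = xv.copy()
        xm[masks[p]] = base
        drops[p] = f_full - forward(model, xm).logits[0, target]
    return drops


def feature_ablation(
    model: MLPModel, x: np.ndarray, target: int,
    config: AttributionConfig | None = None,
) -> np.ndarray:
    """Logit drop from replacing each gene independently with the baseline.

    ``score_i = f(x) - f(x with gene i at baseline)`` for every gene on its
    own; genes already at the baseline value score exactly zero.
    """
    config = config or AttributionConfig()
    X = _as_batch(x, model.n_inputs)
    base = config.baseline_value
    d = model.n_inputs
    eye = np.eye(d, dtype=bool)
    out = np.zeros_like(X)
    for ci in range(X.shape[0]):
        out[ci] = _masked_drops(model, X[ci], target, eye, base)
    return out if np.asarray(x).ndim == 2 else out[0]


def occlusion(
    model: MLPModel, x: np.ndarray, target: int,
    config: AttributionConfig | None = None,
) -> np.ndarray:
    """Sliding-window perturbation along the gene axis.

    A window of ``occlusion_window`` contiguous genes (stride 1, default 3)
    is set to the baseline; each placement records the logit drop
    ``f(x) - f(x_masked)``.  A gene's score is the mean drop over the
    placements covering it; edge genes are covered by fewer placements and
    average over those available.  With window 1 this is exactly feature
    ablation.
    """
    config = config or AttributionConfig()
    config.validate_occlusion(model.n_inputs)
    w = config.occlusion_window
    base = config.baseline_value
    X = _as_batch(x, model.n_inputs)
    n, d = X.shape
    n_place = d - w + 1
    masks = np.zeros((n_place, d), dtype=bool)
    for p in range(n_place):
        masks[p, p : p + w] = True
    lo = np.maximum(0, np.arange(d) - w + 1)
    hi = np.minimum(np.arange(d), n_place - 1)
    out = np.zeros_like(X)
    for ci in range(n):
        drops = _masked_drops(model, X[ci], target, masks, base)
        if w == 1:  # single covering placement; avoid cumsum round-off
            out[ci] = drops
        else:
            dcum = np.concatenate([[0.0], np.cumsum(drops)])
            out[ci] = (dcum[hi + 1] - dcum[lo]) / (hi - lo + 1)
    return out if np.asarray(x).ndim == 2 else out[0]


def lime(
    model: MLPModel, x: np.ndarray, target: int,
    config: AttributionConfig | None = None,
) -> np.ndarray:
    """Local linear surrogate over random binary gene masks.

    ``lime_n_samples`` masks keep each gene independently with probability
    1/2; masked genes are set to 0.  A ridge-regularized linear model
    (uniform sample weights) is fit from the masks to the target logits of
    the masked inputs; its coefficients are the per-gene scores.
    """
    config = config or AttributionConfig()
    config.validate_lime()
    X = _as_batch(x, model.n_inputs)
    rng = np.random.default_rng(config.seed)
    out = np.zeros_like(X)
    for ci in range(X.shape[0]):
        masks = rng.random((config.lime_n_samples, model.n_inputs)) < 0.5
        if np.all(masks == masks[0]):
            raise ValueError("degenerate LIME design: all masks identical")
        logits = forward(model, masks * X[ci]).logits[:, target]
        surrogate = Ridge(alpha=config.lime_ridge, fit_intercept=True)
        surrogate.fit(masks.astype(float), logits)
        out[ci] = surrogate.coef_
    return out if np.asarray(x).ndim == 2 else out[0]


_DISPATCH = {
    "LayerRelProp": layer_relprop,
    "DeepLIFT": deeplift,
    "GradientShap": gradient_shap,
    "Occlusion": occlusion,
    "FeatureAblation": feature_ablation,
    "LIME": lime,
}


def attribute(
    model: MLPModel, x: np.ndarray, target: int, method: str,
    config: AttributionConfig | None = None, target_label=None,
) -> AttributionMatrix:
    """Dispatch to one of the six methods; returns an AttributionMatrix."""
    if method not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    config = config or AttributionConfig()
    scores = _DISPATCH[method](model, np.atleast_2d(np.asarray(x, dtype=float)),
                               target, config)
    return AttributionMatrix(
        scores=scores, method=method,
        target_class=target if target_label is None else target_label,
        config=config,
    )
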