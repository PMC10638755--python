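"""Feed-forward cell-type classifier with a transparent forward contract.

The fixed architecture is three fully connected layers — genes -> 1024 ->
512 -> cell types — with LeakyReLU then ReLU hidden activations (both ReLU
in ``lrp_mode``, which the relevance-propagation attribution requires) and
softmax applied only at loss/prediction time.  The network is implemented
directly on NumPy arrays because every attribution algorithm needs the
per-layer weights, pre-activations and post-activations; :class:`ForwardTrace`
caches all of them.

Training is plain minibatch SGD-style optimization with Adam (lr 1e-3) on
the cross-entropy of the softmax outputs, batch size 64, 20 epochs by
default, fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEAKY_SLOPE = 0.01
HIDDEN_SIZES = (1024, 512)


@dataclass
class Layer:
    W: np.ndarray  # (n_in, n_out)
    b: np.ndarray  # (n_out,)


@dataclass
class MLPModel:
    """Explicit layer weights/biases plus hidden activation kinds."""

    layers: list
    activations: list  # per hidden layer, "leaky_relu" or "relu"
    n_inputs: int
    n_outputs: int

    def __post_init__(self):
        dims = [self.n_inputs]
        for lay in self.layers:
            if lay.W.shape[0] != dims[-1]:
                raise ValueError("layer dimensions do not chain")
            dims.append(lay.W.shape[1])
        if dims[-1] != self.n_outputs:
            raise ValueError("output layer size mismatch")
        if len(self.activations) != len(self.layers) - 1:
            raise ValueError("one hidden activation per hidden layer")
        for a in self.activations:
            if a not in ("relu", "leaky_relu"):
                raise ValueError(f"unknown activation {a!r}")

    def copy(self) -> "MLPModel":
        return MLPModel(
            [Layer(l.W.copy(), l.b.copy()) for l in self.layers],
            list(self.activations), self.n_inputs, self.n_outputs,
        )

    def is_relu_only(self) -> bool:
        return all(a == "relu" for a in self.activations)


@dataclass
class ForwardTrace:
    """Cached forward pass: pre/post activations per layer, logits, probs."""

    x: np.ndarray                 # (n, n_inputs)
    pre_activations: list         # z per layer, (n, width)
    post_activations: list        # a per layer; last equals logits
    logits: np.ndarray            # (n, n_outputs)
    probabilities: np.ndarray     # softmax(logits)


def _act(kind: str, z: np.ndarray) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return np.where(z > 0, z, LEAKY_SLOPE * z)


def _act_deriv(kind: str, z: np.ndarray) -> np.ndarray:
    slope = 0.0 if kind == "relu" else LEAKY_SLOPE
    return np.where(z > 0, 1.0, slope)


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def build_model(
    n_genes: int,
    n_classes: int,
    hidden_sizes: tuple = HIDDEN_SIZES,
    lrp_mode: bool = False,
    seed: int = 0,
) -> MLPModel:
    """Paper-default architecture with seeded Kaiming-uniform init.

    ``lrp_mode`` swaps the first hidden activation from LeakyReLU to ReLU
    so that relevance propagation sees a ReLU-only network.
    """
    if n_genes < 1 or n_classes < 1:
        raise ValueError("need at least one input and one output")
    rng = np.random.default_rng(seed)
    dims = [n_genes, *hidden_sizes, n_classes]
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / d_in)  # Kaiming-uniform for ReLU-family fan-in
        layers.append(Layer(rng.uniform(-bound, bound, size=(d_in, d_out)),
                            np.zeros(d_out)))
    acts = ["relu" if lrp_mode else "leaky_relu"] + ["relu"] * (len(hidden_sizes) - 1)
    acts = acts[: len(hidden_sizes)]
    return MLPModel(layers, acts, n_genes, n_classes)


def _as_batch(x: np.ndarray, n_inputs: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.shape[1] != n_inputs:
        raise ValueError(f"input has {x.shape[1]} features, model expects {n_inputs}")
    return x


def forward(model: MLPModel, x: np.ndarray) -> ForwardTrace:
    """Forward pass with full per-layer caching; accepts a vector or batch."""
    a = _as_batch(x, model.n_inputs)
    x0 = a
    pre, post = [], []
    n_layers = len(model.layers)
    for i, lay in enumerate(model.layers):
        z = a @ lay.W + lay.b
        pre.append(z)
        a = _act(model.activations[i], z) if i < n_layers - 1 else z
        post.append(a)
    logits = post[-1]
    return ForwardTrace(x0, pre, post, logits, softmax(logits))


def input_gradient(model: MLPModel, x: np.ndarray, target: int) -> np.ndarray:
    """Gradient of the target-class logit with respect to the input.

    Returns an array shaped like the (batched) input.
    """
    tr = forward(model, x)
    n = tr.logits.shape[0]
    g = np.zeros_like(tr.logits)
    g[:, target] = 1.0
    n_layers = len(model.layers)
    for i in range(n_layers - 1, -1, -1):
        if i < n_layers - 1:
            g = g * _act_deriv(model.activations[i], tr.pre_activations[i])
        g = g @ model.layers[i].W.T
    return g if np.asarray(x).ndim == 2 else g[0]


def _loss_and_grads(model: MLPModel, xb: np.ndarray, yb: np.ndarray):
    tr = forward(model, xb)
    n = xb.shape[0]
    p = tr.probabilities
    eps = 1e-12
    loss = -np.log(p[np.arange(n), yb] + eps).mean()
    g = p.copy()
    g[np.arange(n), yb] -= 1.0
    g /= n
    grads = []
    n_layers = len(model.layers)
    for i in range(n_layers - 1, -1, -1):
        a_prev = tr.post_activations[i - 1] if i > 0 else tr.x
        gW = a_prev.T @ g
        gb = g.sum(axis=0)
        grads.append((gW, gb))
        if i > 0:
            g = (g @ model.layers[i].W.T) * _act_deriv(
                model.activations[i - 1], tr.pre_activations[i - 1]
            )
    grads.reverse()
    return loss, grads


def train(
    model: MLPModel,
    values: np.ndarray,
    labels: np.ndarray,
    epochs: int = 20,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
) -> tuple[MLPModel, list]:
    """Train on cells x genes values with integer class labels.

    ``values`` is (n_cells, n_genes); ``labels`` integer class indices in
    ``[0, n_outputs)``.  Returns a trained copy of the model plus the
    per-epoch mean cross-entropy history; the input model is not mutated.
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least two classes")
    model = model.copy()
    rng = np.random.default_rng(seed)
    # Adam state
    m_t = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in model.layers]
    v_t = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in model.layers]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = _loss_and_grads(model, X[idx], y[idx])
            losses.append(loss)
            step += 1
            for li, (gW, gb) in enumerate(grads):
                mW, mb = m_t[li]
                vW, vb = v_t[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m_t[li], v_t[li] = (mW, mb), (vW, vb)
                bc1 = 1 - beta1**step
                bc2 = 1 - beta2**step
                model.layers[li].W -= lr * (mW / bc1) / (np.sqrt(vW / bc2) + eps)
                model.layers[li].b -= lr * (mb / bc1) / (np.sqrt(vb / bc2) + eps)
        history.append(float(np.mean(losses)))
    return model, history


def predict(model: MLPModel, values: np.ndarray) -> np.ndarray:
    """Argmax class indices for cells x genes values."""
    return forward(model, values).logits.argmax(axis=1)


def save_model(model: MLPModel, path: str, **metadata) -> None:
    """Self-describing checkpoint (NumPy archive, text-free metadata)."""
    arrays = {}
    for i, lay in enumerate(model.layers):
        arrays[f"W{i}"] = lay.W
        arrays[f"b{i}"] = lay.b
    arrays["activations"] = np.array(model.activations)
    arrays["meta_keys"] = np.array(sorted(metadata))
    for k, v in metadata.items():
        arrays[f"meta_{k}"] = np.array(v)
    np.savez(path, **arrays)


def load_model(path: str) -> MLPModel:
    with np.load(path, allow_pickle=False) as npz:
        acts = [str(a) for a in npz["activations"]]
        layers = []
        i = 0
        while f"W{i}" in npz:
            layers.append(Layer(npz[f"W{i}"], npz[f"b{i}"]))
            i += 1
    return MLPModel(layers, acts, layers[0].W.shape[0], layers[-1].W.shape[1])
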