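"""Train the classifier and compare the six attribution methods on one cell.

The network is genes -> 1024 -> 512 -> types (LeakyReLU/ReLU hidden
activations).  Each attribution method scores every gene's contribution to
the pre-softmax logit of a target cell type; two algebraic identities are
shown: DeepLIFT scores sum exactly to the logit difference from the
all-zero reference, and relevance propagation conserves the explained logit.
"""

import numpy as np

from scattrib import (
    AttributionConfig, SyntheticSpec, attribute, build_model, forward,
    generate, log_norm, train,
)
from scattrib.ranking import class_order

counts, truth = generate(SyntheticSpec(n_genes=500, n_cell_types=4,
                                       cells_per_type=80, markers_per_type=8,
                                       log2_effect_size=3.0, seed=2))
ln = log_norm(counts)
types = class_order(ln.cell_type)
y = np.array([types.index(t) for t in ln.cell_type])

model = build_model(ln.n_genes, len(types), seed=0)
model, history = train(model, ln.values.T, y, epochs=20, seed=0)
print(f"training cross-entropy: {history[0]:.3f} -> {history[-1]:.4f}")

cell = ln.values.T[0]          # one cell of the first type
target = 0
logit = forward(model, cell).logits[0, target]
t0 = forward(model, np.zeros(ln.n_genes)).logits[0, target]
print(f"target logit f(x) = {logit:.4f}, reference logit f(0) = {t0:.4f}\n")

cfg = AttributionConfig(seed=0)
for method in ("LayerRelProp", "DeepLIFT", "GradientShap",
               "Occlusion", "FeatureAblation", "LIME"):
    if method == "LayerRelProp":
        # relevance propagation needs the ReLU-only variant of the model
        lrp_model = build_model(ln.n_genes, len(types), lrp_mode=True, seed=0)
        lrp_model, _ = train(lrp_model, ln.values.T, y, epochs=20, seed=0)
        scores = attribute(lrp_model, cell, target, method, cfg).scores[0]
    else:
        scores = attribute(model, cell, target, method, cfg).scores[0]
    top = np.argsort(-scores)[:3]
    print(f"{method:>15}: sum {scores.sum():8.4f} | top genes "
          + ", ".join(f"{ln.gene_ids[g]} ({scores[g]:.3f})" for g in top))

print("\nDeepLIFT's sum equals f(x) - f(0) exactly (summation-to-delta);")
print("LayerRelProp's sum approximates its own model's logit (conservation).")
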