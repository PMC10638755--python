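"""Full protocol: split, select marker genes, classify, score one-vs-all.

A dataset is split 50/50 by cell type; the classifier is trained on the
training half; genes are ranked per cell type by summing DeepLIFT scores
over that type's cells; the union of each type's top-10 genes feeds a
KNN (k = 7) classifier evaluated one-vs-all on the held-out half.  The
Wilcoxon rank-sum baseline is run on the same split for comparison.
"""

from scattrib import (
    SyntheticSpec, classify_and_score, filter_low_expression, generate,
    log_norm, split_train_test, top_union,
)
from scattrib.bench import rank_with_method

counts, truth = generate(SyntheticSpec(n_genes=1000, n_cell_types=5,
                                       cells_per_type=120, markers_per_type=10,
                                       log2_effect_size=2.0, seed=3))
ln = filter_low_expression(log_norm(counts))
train_half, test_half = split_train_test(ln, seed=3)

truth_map = truth.set_index("gene_id")["marker_of"]
for method in ("DeepLIFT", "Wilcoxon"):
    rankings = rank_with_method(train_half, method, seed=3)
    hits = [len(set(truth_map.index[truth_map == r.cell_type]) & r.top(10))
            for r in rankings]
    genes = sorted(top_union(rankings, 10))
    report = classify_and_score(train_half, test_half, genes, "KNN", seed=3)
    print(f"{method:>9}: planted markers in each type's top-10 {hits}; "
          f"union of {len(genes)} genes -> macro-F1 {report.macro_f1:.3f} "
          f"(sens {report.macro('sensitivity'):.3f}, "
          f"spec {report.macro('specificity'):.3f})")
print("\nBoth selectors recover the planted markers; F1 near 1 means the")
print("selected genes separate the five cell types almost perfectly.")
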