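"""Utility, reproducibility and concordance metrics for selected genes.

Classification utility follows a one-vs-all protocol: a KNN (k = 7) or SVM
classifier is fit on the training half of a dataset restricted to the
selected genes; per cell type TP/FP/TN/FN are counted on the test half and
turned into F1 = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP); macro metrics are unweighted means over types.

Reproducibility is the pairwise Pearson correlation of per-gene statistics
across repeatedly sampled datasets, and concordance between rankings is the
Jaccard index of their top-k gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .io_prep import LogNormMatrix
from .ranking import GeneRanking


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 0.0


@dataclass
class EvalReport:
    """Per-class and macro-averaged one-vs-all metrics for one run."""

    classifier: str
    k_genes: int
    per_class: dict            # label -> ConfusionCounts
    split: str = ""
    seed: int = 0
    classifier_params: dict = field(default_factory=dict)

    def class_metric(self, label, metric: str) -> float:
        return getattr(self.per_class[label], metric)()

    def macro(self, metric: str) -> float:
        vals = [getattr(c, metric)() for c in self.per_class.values()]
        return float(np.mean(vals))

    @property
    def macro_f1(self) -> float:
        return self.macro("f1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, c in self.per_class.items():
            for metric in ("f1", "sensitivity", "specificity"):
                rows.append((self.classifier, self.k_genes, label, metric,
                             getattr(c, metric)()))
        return pd.DataFrame(rows, columns=[
            "classifier", "k_genes", "cell_type", "metric", "value"
        ])


def split_train_test(
    data: LogNormMatrix, fraction: float = 0.5, seed: int = 0,
) -> tuple[LogNormMatrix, LogNormMatrix]:
    """Stratified-by-type random split into train/test (default 50/50).

    For odd type sizes the train side receives the floor of
    ``fraction * size`` (the library splitter's rounding); the split is
    disjoint and exhaustive.
    """
    labels = data.cell_type
    sizes = pd.Series(labels).value_counts()
    if (sizes < 2).any():
        raise ValueError("every cell type needs at least 2 cells to split")
    idx = np.arange(data.n_cells)
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=labels, random_state=seed
    )
    def _take(ix):
        ix = np.sort(ix)
        meta = data.cell_meta.iloc[ix].reset_index(drop=True) if data.cell_meta is not None else None
        return LogNormMatrix(
            values=data.values[:, ix], size_factors=data.size_factors[ix],
            gene_ids=data.gene_ids, cell_ids=data.cell_ids[ix],
            cell_type=data.cell_type[ix], cell_meta=meta,
        )
    return _take(train_idx), _take(test_idx)


def one_vs_all_counts(y_true: np.ndarray, y_pred: np.ndarray, labels) -> dict:
    """Per-class one-vs-all TP/FP/TN/FN from multiclass predictions."""
    out = {}
    n = len(y_true)
    for lab in labels:
        t = y_true == lab
        p = y_pred == lab
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        out[lab] = ConfusionCounts(tp=tp, fp=fp, tn=n - tp - fp - fn, fn=fn)
    return out


def _make_classifier(name: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if name == "KNN":
        params.setdefault("n_neighbors", 7)
        return KNeighborsClassifier(**params)
    if name == "SVM":
        params.setdefault("kernel", "rbf")
        return SVC(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r} (KNN or SVM)")


def classify_and_score(
    train: LogNormMatrix,
    test: LogNormMatrix,
    gene_set,
    classifier: str = "KNN",
    seed: int = 0,
    classifier_params: dict | None = None,
) -> EvalReport:
    """Fit on the selected genes, score one-vs-all on the test half."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    pos = {g: i for i, g in enumerate(train.gene_ids)}
    missing = [g for g in gene_set if g not in pos]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing[:5]}")
    cols = np.array([pos[g] for g in gene_set])
    clf = _make_classifier(classifier, seed, classifier_params)
    clf.fit(train.values[cols].T, train.cell_type.astype(str))
    pred = clf.predict(test.values[cols].T)
    labels = train.cell_types()
    counts = one_vs_all_counts(test.cell_type.astype(str), pred,
                               [str(l) for l in labels])
    return EvalReport(
        classifier=classifier, k_genes=len(gene_set), per_class=counts,
        split="train/test", seed=seed,
        classifier_params=getattr(clf, "get_params", dict)(),
    )


def slope_coefficient(pairs) -> tuple[float, float]:
    """Ordinary least squares slope and intercept for (setting, F1) pairs."""
    pairs = list(pairs)
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct setting values")
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)


def reproducibility_pearson(score_vectors, use_ranks: bool = False):
    """All pairwise Pearson correlations of per-gene statistics.

    ``score_vectors`` are per-gene importance statistics from datasets
    sharing one gene axis.  With ``use_ranks`` the vectors are rank-
    transformed first (Spearman-style).  Constant vectors make the
    coefficient undefined; such pairs are set to NaN and excluded from the
    returned summary of off-diagonal coefficients.
    """
    vecs = [np.asarray(v, dtype=float) for v in score_vectors]
    d = len(vecs[0])
    if any(len(v) != d for v in vecs):
        raise ValueError("score vectors must share one gene axis")
    if use_ranks:
        from scipy.stats import rankdata
        vecs = [rankdata(v) for v in vecs]
    n = len(vecs)
    mat = np.full((n, n), np.nan)
    pair_vals = []
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            si, sj = np.std(vecs[i]), np.std(vecs[j])
            if si == 0 or sj == 0:
                continue  # undefined; left NaN
            r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
            mat[i, j] = mat[j, i] = r
            pair_vals.append(r)
    return mat, np.array(pair_vals)


def jaccard_topk(ranking_a: GeneRanking, ranking_b: GeneRanking, k: int) -> float:
    """Jaccard index |A∩B| / |A∪B| of the two top-k gene sets."""
    a, b = ranking_a.top(k), ranking_b.top(k)
    return len(a & b) / len(a | b)


def pseudobulk(
    data: LogNormMatrix, condition_col: str = "condition",
    sample_col: str | None = None, n_pseudo: int = 10, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average cells into pseudo-bulk profiles per (sample, condition) group.

    When no sample column exists, cells of each condition are randomly
    partitioned into ``n_pseudo`` pseudo-replicates so cross-validation has
    multiple samples per condition.  Returns (profiles genes x groups,
    condition label per group).
    """
    if data.cell_meta is None or condition_col not in data.cell_meta.columns:
        raise ValueError(f"no {condition_col!r} column in cell metadata")
    cond = data.cell_meta[condition_col].to_numpy()
    if len(pd.unique(cond)) < 2:
        raise ValueError("need at least two conditions")
    rng = np.random.default_rng(seed)
    groups = []
    labels = []
    if sample_col is not None and sample_col in data.cell_meta.columns:
        samp = data.cell_meta[sample_col].to_numpy()
        for key in pd.unique(list(zip(samp, cond))):
            mask = (samp == key[0]) & (cond == key[1])
            groups.append(data.values[:, mask].mean(axis=1))
            labels.append(key[1])
    else:
        for c in pd.unique(cond):
            idx = rng.permutation(np.flatnonzero(cond == c))
            for part in np.array_split(idx, min(n_pseudo, len(idx))):
                if len(part):
                    groups.append(data.values[:, part].mean(axis=1))
                    labels.append(c)
    return np.column_stack(groups), np.asarray(labels, dtype=object)


def pseudobulk_condition_eval(
    data: LogNormMatrix,
    rankings: list[GeneRanking],
    k: int = 10,
    condition_col: str = "condition",
    sample_col: str | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean F1 of KNN (k = 7) condition classification on pseudo-bulk data.

    Top-``k`` genes are pooled over the per-cell-type rankings; pseudo-bulk
    profiles are classified under stratified ``n_folds``-fold CV and the
    mean one-vs-all macro-F1 over folds is returned.
    """
    from .ranking import top_union

    genes = sorted(top_union(rankings, k))
    profiles, cond = pseudobulk(
        data, condition_col=condition_col, sample_col=sample_col, seed=seed
    )
    sizes = pd.Series(cond).value_counts()
    if (sizes < n_folds).any():
        raise ValueError("each condition needs at least one sample per fold")
    pos = {g: i for i, g in enumerate(data.gene_ids)}
    Xg = profiles[[pos[g] for g in genes], :].T
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    f1s = []
    for tr, te in skf.split(Xg, cond.astype(str)):
        n_nb = min(7, len(tr))
        clf = KNeighborsClassifier(n_neighbors=n_nb)
        clf.fit(Xg[tr], cond[tr].astype(str))
        pred = clf.predict(Xg[te])
        counts = one_vs_all_counts(cond[te].astype(str), pred,
                                   sorted(set(cond.astype(str))))
        f1s.append(float(np.mean([c.f1() for c in counts.values()])))
    return float(np.mean(f1s))
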