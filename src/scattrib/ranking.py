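"""Per-cell-type gene rankings: attribution aggregation and Wilcoxon baseline.

The deep-learning workflow trains one classifier on all cell types, then for
each cell type computes attributions (target = that type) for every cell of
the type, sums the per-cell scores into a cumulative importance per gene,
and ranks genes by descending cumulative score.  Ties break by gene-id
lexicographic order and the break is recorded.

The traditional baseline ranks genes per cell type by a one-vs-rest
Wilcoxon rank-sum z statistic (midranks, tie-corrected variance, continuity
correction), upregulated genes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import AttributionConfig, _DISPATCH, METHODS
from .io_prep import LogNormMatrix
from .mlp import MLPModel


@dataclass
class GeneRanking:
    """Ordered gene list for one cell type and one method."""

    cell_type: object
    method: str
    ordered_genes: np.ndarray        # gene ids, best first
    cumulative_scores: np.ndarray    # aligned with ordered_genes
    tie_policy: str = "gene_id_lexicographic"

    def top(self, k: int) -> set:
        if k > len(self.ordered_genes):
            raise ValueError(f"k={k} exceeds the {len(self.ordered_genes)}-gene axis")
        return set(self.ordered_genes[:k])


def _order_by_score(gene_ids: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, gene id ascending on ties."""
    # np.lexsort: last key is primary
    return np.lexsort((np.asarray(gene_ids, dtype=str), -np.asarray(scores)))


def class_order(labels) -> list:
    """Canonical class encoding: sorted unique labels.

    Used both when training the classifier and when picking attribution
    target indices, so rankings do not depend on cell order in the matrix.
    """
    return sorted(set(labels))


def rank_genes(
    model: MLPModel,
    data: LogNormMatrix,
    method: str,
    config: AttributionConfig | None = None,
    class_labels: list | None = None,
) -> list[GeneRanking]:
    """Attribution-based ranking, one :class:`GeneRanking` per cell type.

    For each cell type the target class is that type's index in
    ``class_labels`` (defaulting to the canonical sorted order, which must
    match the encoding the model was trained with); attributions are
    computed for the cells of that type only and summed per gene.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    config = config or AttributionConfig()
    if model.n_inputs != data.n_genes:
        raise ValueError("model gene axis does not match the data")
    types = class_labels if class_labels is not None else class_order(data.cell_type)
    X = data.values.T  # cells x genes
    rankings = []
    for ti, t in enumerate(types):
        cells = np.flatnonzero(data.cell_type == t)
        if len(cells) == 0:
            raise ValueError(f"cell type {t!r} absent from data")
        # canonical cell order makes the sum exactly order-invariant
        cells = cells[np.argsort(data.cell_ids[cells].astype(str))]
        scores = _DISPATCH[method](model, X[cells], ti, config)
        cum = scores.sum(axis=0)
        order = _order_by_score(data.gene_ids, cum)
        rankings.append(GeneRanking(
            cell_type=t, method=method,
            ordered_genes=data.gene_ids[order],
            cumulative_scores=cum[order],
        ))
    return rankings


def top_union(rankings: list[GeneRanking], k: int) -> set:
    """Union over cell types of each ranking's top-k genes (set semantics)."""
    out: set = set()
    for r in rankings:
        out |= r.top(k)
    return out


def wilcoxon_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected, continuity-corrected normal-approximation z statistic.

    Rank-sum of ``x`` within the pooled sample using midranks; z is signed
    so that larger values in ``x`` give positive z.  Returns 0 when the
    tie-corrected variance vanishes (all values identical).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = ranks[:n1].sum()
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 0.0
    diff = W - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    return float((diff - cc) / np.sqrt(var))


def wilcoxon_one_sided_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """One-sided normal-approximation p with direction-specific continuity.

    ``alternative="greater"`` tests whether ``x`` is stochastically larger:
    ``p = sf((W - mu - 1/2) / sigma)``; ``"less"`` uses
    ``cdf((W - mu + 1/2) / sigma)``.  Ties use midranks and the corrected
    variance as in :func:`wilcoxon_z`.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = ranks[:n1].sum()
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    sigma = np.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf((W - mu - 0.5) / sigma))
    if alternative == "less":
        return float(stats.norm.cdf((W - mu + 0.5) / sigma))
    raise ValueError("alternative must be 'greater' or 'less'")


def wilcoxon_rank(data: LogNormMatrix) -> list[GeneRanking]:
    """One-vs-rest Wilcoxon ranking per cell type, upregulated first."""
    types = class_order(data.cell_type)
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    rankings = []
    for t in types:
        in_t = data.cell_type == t
        if in_t.sum() < 2 or (~in_t).sum() < 2:
            raise ValueError(f"cell type split for {t!r} has fewer than 2 cells")
        z = np.array([
            wilcoxon_z(data.values[g, in_t], data.values[g, ~in_t])
            for g in range(data.n_genes)
        ])
        order = _order_by_score(data.gene_ids, z)
        rankings.append(GeneRanking(
            cell_type=t, method="Wilcoxon",
            ordered_genes=data.gene_ids[order],
            cumulative_scores=z[order],
        ))
    return rankings


def signed_logp_scores(p_values: np.ndarray, log2_fc: np.ndarray) -> np.ndarray:
    """Ranking transform for external p-value tables: -log10(p) * sign(lfc).

    Useful for ranking results of tools that report only p-values and fold
    changes; p-values are floored at 1e-300 before the log.
    """
    p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    return -np.log10(p) * np.sign(np.asarray(log2_fc, dtype=float))


def rankings_to_frame(rankings: list[GeneRanking]) -> pd.DataFrame:
    """Long-format table: cell_type, method, rank, gene_id, cumulative_score."""
    rows = []
    for r in rankings:
        for i, (g, s) in enumerate(zip(r.ordered_genes, r.cumulative_scores), 1):
            rows.append((r.cell_type, r.method, i, g, s))
    return pd.DataFrame(rows, columns=[
        "cell_type", "method", "rank", "gene_id", "cumulative_score"
    ])
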