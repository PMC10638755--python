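"""Seeded synthetic scRNA-seq count generator with planted ground truth.

Emulates the properties of atlas-derived datasets that the rest of the
toolkit consumes: several discrete cell types, negative-binomial counts with
per-cell library-size variation, a small disjoint set of marker genes
upregulated in exactly one cell type each, and a large majority of
uninformative genes.  Optionally a second, type-independent "condition"
axis for pseudo-bulk classification tests.

Negative binomial parameterization: mean ``mu``, dispersion ``theta`` with
variance ``mu + mu^2 / theta`` (gamma-Poisson mixture; larger ``theta`` means
less overdispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_prep import CountMatrix


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``cells_per_type`` may be a scalar or a per-type sequence (imbalanced
    designs).  ``log2_effect_size`` multiplies a marker gene's mean by
    ``2**effect`` in its own cell type only.  ``condition_effect`` (log2),
    if nonzero, upregulates ``n_condition_genes`` non-marker genes in the
    second of two condition groups assigned independently of cell type.
    """

    n_genes: int = 2000
    n_cell_types: int = 10
    cells_per_type: int | tuple | list = 200
    markers_per_type: int = 10
    log2_effect_size: float = 2.0
    nb_dispersion: float = 2.0
    library_size_mean: float = 1.0
    library_size_sd: float = 0.3
    condition_effect: float = 0.0
    n_condition_genes: int = 20
    with_conditions: bool = False  # force condition labels even at effect 0
    seed: int = 0

    def per_type_counts(self) -> np.ndarray:
        if np.isscalar(self.cells_per_type):
            return np.full(self.n_cell_types, int(self.cells_per_type))
        arr = np.asarray(self.cells_per_type, dtype=int)
        if len(arr) != self.n_cell_types:
            raise ValueError("cells_per_type length must equal n_cell_types")
        return arr

    def validate(self) -> None:
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("marker sets exceed the gene dimension")
        if np.any(self.per_type_counts() < 1):
            raise ValueError("every cell type needs at least one cell")
        if self.log2_effect_size < 0:
            raise ValueError("effect size must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate counts and the ground-truth marker table.

    Baseline gene means are log-normal; marker genes draw their baseline
    from a moderately-expressed log-normal (median 1) so that planted
    markers behave like real marker genes rather than near-silent ones.
    Counts are gamma-Poisson with per-cell library-size scaling.

    Returns the :class:`CountMatrix` and a truth table with columns
    ``gene_id`` and ``marker_of`` (the cell-type label, or NA).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_per_type = spec.per_type_counts()
    n_cells = int(n_per_type.sum())
    types = [f"type{t:02d}" for t in range(spec.n_cell_types)]
    labels = np.repeat(types, n_per_type)

    base_mean = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=spec.n_genes)
    marker_gene_idx = rng.choice(
        spec.n_genes, size=spec.markers_per_type * spec.n_cell_types, replace=False
    )
    base_mean[marker_gene_idx] = rng.lognormal(
        mean=0.0, sigma=0.5, size=len(marker_gene_idx)
    )

    marker_of = np.full(spec.n_genes, None, dtype=object)
    # mean matrix per (gene, type): baseline, markers boosted in own type
    type_mean = np.tile(base_mean[:, None], (1, spec.n_cell_types))
    for t in range(spec.n_cell_types):
        genes_t = marker_gene_idx[
            t * spec.markers_per_type : (t + 1) * spec.markers_per_type
        ]
        type_mean[genes_t, t] *= 2.0 ** spec.log2_effect_size
        marker_of[genes_t] = types[t]

    lib = spec.library_size_mean * rng.lognormal(
        mean=-0.5 * spec.library_size_sd**2, sigma=spec.library_size_sd, size=n_cells
    )

    condition = None
    if spec.condition_effect != 0.0 or spec.with_conditions:
        condition = np.where(rng.random(n_cells) < 0.5, "healthy", "inflamed")
        non_marker = np.setdiff1d(np.arange(spec.n_genes), marker_gene_idx)
        cond_genes = rng.choice(
            non_marker, size=min(spec.n_condition_genes, len(non_marker)), replace=False
        )

    type_index = np.repeat(np.arange(spec.n_cell_types), n_per_type)
    mu = type_mean[:, type_index] * lib[None, :]
    if condition is not None:
        boost = np.ones((spec.n_genes, n_cells))
        boost[np.ix_(cond_genes, condition == "inflamed")] = 2.0 ** spec.condition_effect
        mu = mu * boost

    theta = spec.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    meta = None
    if condition is not None:
        meta = pd.DataFrame({"condition": condition})
    cm = CountMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i:05d}" for i in range(spec.n_genes)], dtype=object),
        cell_ids=np.array([f"c{i:05d}" for i in range(n_cells)], dtype=object),
        cell_type=labels.astype(object),
        cell_meta=meta,
    )
    truth = pd.DataFrame({"gene_id": cm.gene_ids, "marker_of": marker_of})
    return cm, truth


def make_separable(
    n_genes: int = 200,
    n_cell_types: int = 3,
    cells_per_type: int = 100,
    markers_per_type: int = 5,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Convenience wrapper: strongly separated types for classifier tests.

    Large effect (log2 effect 4) and low overdispersion (theta = 10) make
    the types linearly separable in log-normalized space.
    """
    if n_cell_types < 2:
        raise ValueError("classifier fixtures need at least two cell types")
    spec = SyntheticSpec(
        n_genes=n_genes,
        n_cell_types=n_cell_types,
        cells_per_type=cells_per_type,
        markers_per_type=markers_per_type,
        log2_effect_size=4.0,
        nb_dispersion=10.0,
        seed=seed,
    )
    return generate(spec)
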