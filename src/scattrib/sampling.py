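"""Dataset-sampling designs over a preprocessed atlas.

Three benchmark designs plus a reproducibility series are supported:

- ``vary_types``: 5/10/15/20 cell types, 200 cells each;
- ``vary_cells``: 10 or 20 cell types, 50..250 cells per type (step 50);
- ``imbalance``: 10 or 20 cell types, half major (200 cells) and half minor
  with major:minor ratios 2:1, 4:1, 10:1 (minor = 100/50/20 cells);
- ``reproducibility``: one fixed selection of cell types, repeatedly
  re-sampling the cells only.

Every design setting is repeated (10 repetitions by default) per atlas;
the default grids enumerate 80, 200 and 120 datasets respectively.
Each dataset spec carries a seed derived deterministically from a single
base seed so any dataset is reconstructible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_prep import CountMatrix

DESIGN_KINDS = ("vary_types", "vary_cells", "imbalance", "reproducibility")
_KIND_CODE = {k: i for i, k in enumerate(DESIGN_KINDS)}


@dataclass(frozen=True)
class SamplingDesign:
    """One setting of a sampling design (before repetition)."""

    design_kind: str
    atlas_id: str
    n_cell_types: int
    n_cells_major: int
    n_cells_minor: int
    repetitions: int
    seed: int  # base seed of the whole grid

    def __post_init__(self):
        if self.design_kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.design_kind!r}")
        if self.n_cell_types < 2:
            raise ValueError("designs need at least two cell types")
        if min(self.n_cells_major, self.n_cells_minor) < 1:
            raise ValueError("cells per type must be >= 1")
        if self.design_kind == "imbalance" and self.n_cell_types % 2:
            raise ValueError("imbalance designs need an even number of cell types")


@dataclass
class DatasetSpec:
    """One concrete dataset to sample: a design setting plus repetition.

    ``chosen_cell_types`` and ``per_type_cell_counts`` are filled when the
    spec is resolved against an atlas (``sample_dataset``); until then only
    the derived ``seed`` pins the choice.
    """

    design: SamplingDesign
    repetition_index: int
    seed: int
    chosen_cell_types: list | None = None
    per_type_cell_counts: dict | None = None

    def requested_counts(self) -> list[int]:
        d = self.design
        if d.design_kind == "imbalance":
            half = d.n_cell_types // 2
            return [d.n_cells_major] * half + [d.n_cells_minor] * half
        return [d.n_cells_major] * d.n_cell_types


def derive_seed(base_seed: int, design_kind: str, setting_index: int, rep: int) -> int:
    """Stable per-dataset seed below 2**31, derived from the base seed."""
    ss = np.random.SeedSequence(
        [int(base_seed), _KIND_CODE[design_kind], int(setting_index), int(rep)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class DesignGrid:
    """Benchmark grid configuration (atlases x settings x repetitions)."""

    atlases: list = field(default_factory=lambda: ["tabula_muris", "tabula_sapiens"])
    design_kinds: list = field(default_factory=lambda: ["vary_types", "vary_cells", "imbalance"])
    vary_types_grid: list = field(default_factory=lambda: [5, 10, 15, 20])
    vary_types_cells: int = 200
    vary_cells_types: list = field(default_factory=lambda: [10, 20])
    vary_cells_grid: list = field(default_factory=lambda: [50, 100, 150, 200, 250])
    imbalance_types: list = field(default_factory=lambda: [10, 20])
    imbalance_ratios: list = field(default_factory=lambda: [2, 4, 10])
    imbalance_major_cells: int = 200
    repetitions: int = 10
    base_seed: int = 0


def enumerate_designs(config: DesignGrid) -> list[DatasetSpec]:
    """Full deterministic cross-product of the grid: one spec per dataset."""
    specs: list[DatasetSpec] = []
    for kind in config.design_kinds:
        if kind == "vary_types":
            settings = [
                (atlas, n, config.vary_types_cells, config.vary_types_cells)
                for atlas in config.atlases
                for n in config.vary_types_grid
            ]
        elif kind == "vary_cells":
            settings = [
                (atlas, n, c, c)
                for atlas in config.atlases
                for n in config.vary_cells_types
                for c in config.vary_cells_grid
            ]
        elif kind == "imbalance":
            settings = [
                (atlas, n, config.imbalance_major_cells, config.imbalance_major_cells // r)
                for atlas in config.atlases
                for n in config.imbalance_types
                for r in config.imbalance_ratios
            ]
        else:
            raise ValueError(f"unknown design kind {kind!r}")
        if not settings:
            raise ValueError(f"empty grid for design {kind!r}")
        for si, (atlas, n_types, major, minor) in enumerate(settings):
            design = SamplingDesign(
                design_kind=kind, atlas_id=atlas, n_cell_types=n_types,
                n_cells_major=major, n_cells_minor=minor,
                repetitions=config.repetitions, seed=config.base_seed,
            )
            for rep in range(config.repetitions):
                specs.append(DatasetSpec(
                    design=design, repetition_index=rep,
                    seed=derive_seed(config.base_seed, kind, si, rep),
                ))
    return specs


def specs_manifest(specs: list[DatasetSpec]) -> pd.DataFrame:
    """Tabular audit manifest, one row per dataset spec."""
    return pd.DataFrame([
        {
            "design_kind": s.design.design_kind,
            "atlas_id": s.design.atlas_id,
            "n_cell_types": s.design.n_cell_types,
            "n_cells_major": s.design.n_cells_major,
            "n_cells_minor": s.design.n_cells_minor,
            "repetition": s.repetition_index,
            "seed": s.seed,
        }
        for s in specs
    ])


def _eligible_types(atlas: CountMatrix, min_cells: int) -> list:
    sizes = pd.Series(atlas.cell_type).value_counts()
    return sorted(sizes.index[sizes >= min_cells])


def sample_dataset(atlas: CountMatrix, spec: DatasetSpec) -> CountMatrix:
    """Draw one dataset: types uniformly without replacement, then cells.

    In imbalance designs the first half of the randomly ordered selected
    types are major.  Reproducible from ``spec.seed`` alone; the resolved
    type choice and per-type counts are recorded back onto ``spec``.
    """
    rng = np.random.default_rng(spec.seed)
    wanted = spec.requested_counts()
    need_max = max(wanted)
    if spec.chosen_cell_types is None:
        eligible = _eligible_types(atlas, min_cells=need_max)
        if len(eligible) < spec.design.n_cell_types:
            raise ValueError(
                f"atlas has {len(eligible)} cell types with >= {need_max} cells; "
                f"{spec.design.n_cell_types} requested"
            )
        chosen = list(rng.choice(eligible, size=spec.design.n_cell_types, replace=False))
    else:
        chosen = list(spec.chosen_cell_types)
    idx_parts = []
    counts_map = {}
    for t, n_want in zip(chosen, wanted):
        pool = np.flatnonzero(atlas.cell_type == t)
        if len(pool) < n_want:
            raise ValueError(f"cell type {t!r} has {len(pool)} cells, {n_want} requested")
        take = rng.choice(pool, size=n_want, replace=False)
        idx_parts.append(np.sort(take))
        counts_map[t] = n_want
    spec.chosen_cell_types = chosen
    spec.per_type_cell_counts = counts_map
    return atlas.subset_cells(np.concatenate(idx_parts))


def reproducibility_series(
    atlas: CountMatrix,
    n_types: int = 10,
    n_cells: int = 200,
    reps: int = 10,
    seed: int = 0,
) -> list[CountMatrix]:
    """Datasets sharing one fixed cell-type selection but different cells.

    The cell-type set is drawn once from ``seed``; each repetition re-draws
    only the cells.  Downstream normalization of these datasets must skip
    the low-expression gene filter so all repetitions share the full gene
    axis (the library's benchmark runner does this).
    """
    rng = np.random.default_rng(seed)
    eligible = _eligible_types(atlas, min_cells=n_cells)
    if len(eligible) < n_types:
        raise ValueError("not enough eligible cell types for the series")
    chosen = list(rng.choice(eligible, size=n_types, replace=False))
    design = SamplingDesign(
        design_kind="reproducibility", atlas_id="atlas", n_cell_types=n_types,
        n_cells_major=n_cells, n_cells_minor=n_cells, repetitions=reps, seed=seed,
    )
    out = []
    for rep in range(reps):
        spec = DatasetSpec(
            design=design, repetition_index=rep,
            seed=derive_seed(seed, "reproducibility", 0, rep),
            chosen_cell_types=chosen,
        )
        out.append(sample_dataset(atlas, spec))
    return out
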