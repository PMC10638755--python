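"""Manifest-driven benchmark runs tying the modules together.

``run_benchmark`` executes, for each dataset of a (usually synthetic)
mini-grid and each feature-selection method: normalization and gene
filtering, a stratified 50/50 split, classifier training (for the
attribution methods), per-cell-type gene ranking, top-k union, and one-vs-
all KNN/SVM scoring.  Everything is reproducible from the configuration
plus a base seed; per-dataset failures are recorded and do not abort the
grid.  ``time_methods`` reports informational wall-clock per method,
including data generation/loading and, for the attribution methods, model
training.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io_prep, mlp, ranking, evaluation, synthetic
from .attribution import AttributionConfig, METHODS, GRADIENT_METHODS
from .sampling import derive_seed

KNOWN_METHODS = (*METHODS, "Wilcoxon")


@dataclass
class BenchmarkConfig:
    """Mini-grid over synthetic datasets x methods.

    ``grid`` maps setting names to synthetic generator overrides, e.g.
    ``{"types5": {"n_cell_types": 5}, "types10": {"n_cell_types": 10}}``.
    """

    methods: list = field(default_factory=lambda: ["DeepLIFT", "Wilcoxon"])
    grid: dict = field(default_factory=lambda: {"default": {}})
    repetitions: int = 2
    top_k: int = 10
    classifier: str = "KNN"
    epochs: int = 20
    base_seed: int = 0
    n_genes: int = 500
    n_cell_types: int = 5
    cells_per_type: int = 100
    markers_per_type: int = 10
    log2_effect_size: float = 2.0

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; known: {KNOWN_METHODS}")
        if not self.grid:
            raise ValueError("empty setting grid")

    def dataset_spec(self, setting: str, rep: int) -> synthetic.SyntheticSpec:
        base = dict(
            n_genes=self.n_genes, n_cell_types=self.n_cell_types,
            cells_per_type=self.cells_per_type,
            markers_per_type=self.markers_per_type,
            log2_effect_size=self.log2_effect_size,
        )
        base.update(self.grid[setting])
        idx = sorted(self.grid).index(setting)
        base["seed"] = derive_seed(self.base_seed, "vary_types", idx, rep)
        return synthetic.SyntheticSpec(**base)


def config_digest(config: BenchmarkConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    config_digest: str
    seeds: dict
    stage_seconds: dict
    outputs: dict          # path -> checksum
    errors: dict
    version: str = ""


def rank_with_method(
    data: io_prep.LogNormMatrix, method: str, seed: int, epochs: int = 20,
) -> list[ranking.GeneRanking]:
    """Train (if needed) and rank genes per cell type with one method."""
    if method == "Wilcoxon":
        return ranking.wilcoxon_rank(data)
    types = ranking.class_order(data.cell_type)
    y = np.array([types.index(t) for t in data.cell_type])
    model = mlp.build_model(
        data.n_genes, len(types), lrp_mode=(method == "LayerRelProp"), seed=seed
    )
    model, _ = mlp.train(model, data.values.T, y, epochs=epochs, seed=seed)
    cfg = AttributionConfig(seed=seed)
    return ranking.rank_genes(model, data, method, cfg)


def run_benchmark(config: BenchmarkConfig, out_dir: str) -> tuple[RunManifest, pd.DataFrame]:
    """Run the grid; write metrics.csv + manifest.json under ``out_dir``."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    errors = {}
    stage_seconds = {}
    seeds = {"base_seed": config.base_seed}
    for setting in sorted(config.grid):
        for rep in range(config.repetitions):
            ds_name = f"{setting}/rep{rep}"
            t0 = time.perf_counter()
            spec = config.dataset_spec(setting, rep)
            seeds[ds_name] = spec.seed
            try:
                cm, truth = synthetic.generate(spec)
                ln = io_prep.filter_low_expression(io_prep.log_norm(cm))
                train, test = evaluation.split_train_test(ln, seed=spec.seed)
            except Exception as exc:  # noqa: BLE001 - crash isolation
                errors[ds_name] = repr(exc)
                continue
            stage_seconds[f"{ds_name}/data"] = time.perf_counter() - t0
            for method in config.methods:
                t1 = time.perf_counter()
                try:
                    rks = rank_with_method(train, method, spec.seed, config.epochs)
                    genes = sorted(ranking.top_union(rks, config.top_k))
                    report = evaluation.classify_and_score(
                        train, test, genes, classifier=config.classifier,
                        seed=spec.seed,
                    )
                except Exception as exc:  # noqa: BLE001
                    errors[f"{ds_name}/{method}"] = repr(exc)
                    continue
                stage_seconds[f"{ds_name}/{method}"] = time.perf_counter() - t1
                rows.append({
                    "setting": setting, "repetition": rep, "method": method,
                    "classifier": config.classifier, "top_k": config.top_k,
                    "n_union_genes": len(genes),
                    "macro_f1": report.macro_f1,
                    "macro_sensitivity": report.macro("sensitivity"),
                    "macro_specificity": report.macro("specificity"),
                    "seed": spec.seed,
                })
    metrics = pd.DataFrame(rows)
    metrics_path = os.path.join(out_dir, "metrics.csv")
    metrics.to_csv(metrics_path, index=False)
    outputs = {metrics_path: _file_checksum(metrics_path)}
    manifest = RunManifest(
        config_digest=config_digest(config), seeds=seeds,
        stage_seconds=stage_seconds, outputs=outputs, errors=errors,
        version="0.1.0",
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(asdict(manifest), fh, indent=1)
    return manifest, metrics


def time_methods(config: BenchmarkConfig) -> pd.DataFrame:
    """Informational per-method wall-clock on the grid's first setting.

    Each method's duration includes data generation and normalization; for
    the attribution methods it also includes model training (reported
    separately in ``train_seconds``).  Durations are reported, never
    asserted against thresholds: they are hardware-bound.
    """
    config.validate()
    setting = sorted(config.grid)[0]
    rows = []
    for method in config.methods:
        t0 = time.perf_counter()
        spec = config.dataset_spec(setting, 0)
        cm, _ = synthetic.generate(spec)
        ln = io_prep.filter_low_expression(io_prep.log_norm(cm))
        load_s = time.perf_counter() - t0
        train_s = 0.0
        t1 = time.perf_counter()
        if method == "Wilcoxon":
            ranking.wilcoxon_rank(ln)
        else:
            types = ranking.class_order(ln.cell_type)
            y = np.array([types.index(t) for t in ln.cell_type])
            model = mlp.build_model(
                ln.n_genes, len(types),
                lrp_mode=(method == "LayerRelProp"), seed=spec.seed,
            )
            t_tr = time.perf_counter()
            model, _ = mlp.train(model, ln.values.T, y, epochs=config.epochs,
                                 seed=spec.seed)
            train_s = time.perf_counter() - t_tr
            ranking.rank_genes(model, ln, method, AttributionConfig(seed=spec.seed))
        rows.append({
            "method": method,
            "total_seconds": load_s + (time.perf_counter() - t1),
            "load_seconds": load_s,
            "train_seconds": train_s,
        })
    return pd.DataFrame(rows)


def marker_recovery_study(
    seed: int = 0,
    methods: tuple = GRADIENT_METHODS,
    n_cell_types: int = 10,
    cells_per_type: int = 200,
    markers_per_type: int = 10,
    log2_effect_size: float = 2.0,
    n_genes: int = 2000,
    top_n: int = 20,
    union_k: int = 10,
    epochs: int = 20,
) -> dict:
    """Planted-marker recovery under the benchmark protocol.

    Generates one synthetic dataset at the stated conditions, splits 50/50,
    trains the classifier on the training half, ranks genes per cell type
    with each method, and measures (i) the minimum and mean per-type
    fraction of planted markers recovered in the type's top-``top_n`` and
    (ii) macro-F1 of KNN (k = 7) on the top-``union_k`` union.  Returns a
    dict of results keyed by method plus the shared F1 entries.
    """
    spec = synthetic.SyntheticSpec(
        n_genes=n_genes, n_cell_types=n_cell_types,
        cells_per_type=cells_per_type, markers_per_type=markers_per_type,
        log2_effect_size=log2_effect_size, seed=seed,
    )
    cm, truth = synthetic.generate(spec)
    ln = io_prep.filter_low_expression(io_prep.log_norm(cm))
    train, test = evaluation.split_train_test(ln, seed=seed)
    truth_map = truth.set_index("gene_id")["marker_of"]
    types = ranking.class_order(train.cell_type)
    y = np.array([types.index(t) for t in train.cell_type])
    results: dict = {"n_cells": cm.n_cells, "n_genes_after_filter": ln.n_genes}
    for method in methods:
        model = mlp.build_model(
            train.n_genes, len(types),
            lrp_mode=(method == "LayerRelProp"), seed=seed,
        )
        model, _ = mlp.train(model, train.values.T, y, epochs=epochs, seed=seed)
        rks = ranking.rank_genes(model, train, method, AttributionConfig(seed=seed))
        fracs = []
        for r in rks:
            planted = set(truth_map.index[truth_map == r.cell_type])
            planted &= set(train.gene_ids)  # markers surviving the filter
            hit = len(planted & r.top(top_n))
            fracs.append(hit / markers_per_type)
        genes = sorted(ranking.top_union(rks, union_k))
        report = evaluation.classify_and_score(train, test, genes, "KNN", seed=seed)
        results[method] = {
            "min_marker_recovery": float(np.min(fracs)),
            "mean_marker_recovery": float(np.mean(fracs)),
            "macro_f1_top%d_union" % union_k: report.macro_f1,
        }
    return results
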