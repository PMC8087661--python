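"""End-to-end orchestration: simulate/extract -> PCA -> select -> classify.

One master seed fans out deterministically to every stochastic stage, so a
run is reproducible from its manifest alone. Reports are plain JSON and TSV.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .pca import (
    align_component_signs,
    build_feature_matrix,
    build_single_task_features,
    subject_pca,
    summarize_explained_variance,
)
from .roi import RoiBetaMatrix, extract_roibvals, filter_rois
from .svm import FamilyResult, SvmConfig, compare_feature_sets, default_grid
from .synthetic import SyntheticConfig, generate_dataset, synthetic_atlas
from .tables import FeatureTable

ALL_FAMILIES = ("PC1", "PC2", "PC3", "picture", "sound", "Stroop")


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None  # None -> default study conditions
    data_dir: str | None = None  # pre-extracted beta tables instead of synthetic
    families: tuple[str, ...] = ALL_FAMILIES
    grid_resolution: int = 20
    nested: bool = False
    via_volumes: bool = False  # exercise the voxel extraction round trip


@dataclass
class RunManifest:
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    selected_lambda: dict[str, float] = field(default_factory=dict)
    selected_features: dict[str, list] = field(default_factory=dict)
    svm_params: dict[str, dict] = field(default_factory=dict)
    metrics: dict[str, dict] = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "input_digests": self.input_digests,
            "selected_lambda": self.selected_lambda,
            "selected_features": self.selected_features,
            "svm_params": self.svm_params,
            "metrics": self.metrics,
            "stage_seconds": self.stage_seconds,
        }


def derive_stage_seeds(master: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master).generate_state(2)
    return {"synthetic": int(state[0] % 2**31), "svm": int(state[1] % 2**31)}


def build_feature_tables(
    matrices: list[RoiBetaMatrix],
    labels: np.ndarray,
    families: tuple[str, ...] = ALL_FAMILIES,
) -> dict[str, FeatureTable]:
    """PCA + sign alignment + assembly of every requested feature family."""
    pc_families = [f for f in families if f.startswith("PC")]
    task_families = [f for f in families if not f.startswith("PC")]
    tables: dict[str, FeatureTable] = {}
    pcas = [subject_pca(m) for m in matrices] if pc_families else []
    for fam in pc_families:
        k = int(fam[2:])
        aligned = align_component_signs(pcas, k)
        tables[fam] = build_feature_matrix(aligned, k, labels)
    for fam in task_families:
        tables[fam] = build_single_task_features(matrices, fam, labels)
    return tables


def run_all(config: PipelineConfig, out_dir=None) -> RunManifest:
    """Execute the full pipeline and (optionally) write all reports."""
    seeds = derive_stage_seeds(config.seed)
    manifest = RunManifest(config=_config_snapshot(config), seeds=seeds)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    t0 = time.perf_counter()
    try:
        matrices, labels = _load_inputs(config, seeds, manifest)
        manifest.stage_seconds["inputs"] = time.perf_counter() - t0

        stage = "pca"
        t0 = time.perf_counter()
        tables = build_feature_tables(matrices, labels, config.families)
        pcas = [subject_pca(m) for m in matrices]
        variance_summary = summarize_explained_variance(
            pcas, labels, group_names={1: "PI", 0: "HC"}
        )
        manifest.stage_seconds["pca"] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        svm_config = SvmConfig(
            C_grid=default_grid(config.grid_resolution),
            gamma_grid=default_grid(config.grid_resolution),
        )
        results = compare_feature_sets(
            tables, svm_config, seed=seeds["svm"], nested=config.nested
        )
        manifest.stage_seconds["classify"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for fam, res in results.items():
        if res.lasso_path is not None:
            manifest.selected_lambda[fam] = res.lasso_path.selected_lambda
        manifest.selected_features[fam] = list(res.selected)
        if res.svm is not None:
            manifest.svm_params[fam] = {
                "C": res.svm.best_C,
                "gamma": res.svm.best_gamma,
                "loocv_accuracy": res.svm.accuracy,
            }
        if res.metrics is not None:
            manifest.metrics[fam] = {
                **{k: float(v) for k, v in res.metrics.as_dict().items()},
                "display": res.metrics.display,
                "confusion": {
                    "TP": res.metrics.confusion.tp,
                    "FP": res.metrics.confusion.fp,
                    "TN": res.metrics.confusion.tn,
                    "FN": res.metrics.confusion.fn,
                },
            }

    if out is not None:
        _write_reports(out, manifest, tables, results, variance_summary)
    return manifest


def _load_inputs(config: PipelineConfig, seeds: dict, manifest: RunManifest):
    if config.data_dir is not None:
        matrices, labels = tio.read_dataset_tables(config.data_dir)
        for m in matrices:
            manifest.input_digests[m.participant_id] = _digest(m.values)
    else:
        syn = config.synthetic or SyntheticConfig(seed=seeds["synthetic"])
        if config.synthetic is None:
            manifest.config["synthetic_seed"] = seeds["synthetic"]
        if config.via_volumes:
            syn_v = SyntheticConfig(**{**_syn_kwargs(syn), "voxel_mode": True})
            dataset = generate_dataset(syn_v)
            atlas = synthetic_atlas(syn_v)
            raw = [
                extract_roibvals({t: v for t, v in vols.items()}, atlas, pid)
                for pid, vols in zip(dataset.participant_ids, dataset.volumes)
            ]
            retained = filter_rois(raw, atlas, mode="list")
            matrices = [m.subset(retained) for m in raw]
        else:
            dataset = generate_dataset(syn)
            matrices = dataset.beta_matrices
        labels = dataset.labels
        for m in matrices:
            manifest.input_digests[m.participant_id] = _digest(m.values)
    return matrices, labels


def _write_reports(out, manifest, tables, results, variance_summary) -> None:
    tio.write_json(
        {f: m for f, m in manifest.metrics.items()}, out / "metrics.json"
    )
    tio.write_json(manifest.report(), out / "manifest.json")
    variance_summary.to_csv(out / "explained_variance.tsv", sep="\t", index=False)
    for fam, table in tables.items():
        table.write_tsv(out / f"features_{fam}.tsv")
    for fam, res in results.items():
        if res.lasso_path is None:
            continue
        tio.write_json(
            {
                "family": fam,
                "lambdas": res.lasso_path.lambdas.tolist(),
                "loocv_deviance": res.lasso_path.deviances.tolist(),
                "selected_lambda": res.lasso_path.selected_lambda,
                "selected_features": res.selected,
            },
            out / f"deviance_{fam}.json",
        )


def _digest(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def _syn_kwargs(syn: SyntheticConfig) -> dict:
    return {
        "n_pos": syn.n_pos,
        "n_neg": syn.n_neg,
        "n_rois": syn.n_rois,
        "n_tasks": syn.n_tasks,
        "singular_values": syn.singular_values,
        "effect_rois": syn.effect_rois,
        "effect_size": syn.effect_size,
        "jitter": syn.jitter,
        "noise_sd": syn.noise_sd,
        "seed": syn.seed,
        "voxels_per_roi": syn.voxels_per_roi,
    }


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = {
        "seed": config.seed,
        "families": list(config.families),
        "grid_resolution": config.grid_resolution,
        "nested": config.nested,
        "via_volumes": config.via_volumes,
        "data_dir": config.data_dir,
    }
    if config.synthetic is not None:
        snap["synthetic"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in _syn_kwargs(config.synthetic).items()
        }
    return snap
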