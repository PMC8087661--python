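"""Reading and writing the pipeline's file formats.

Beta matrices travel as wide TSV (ROI rows, task columns, one file per
participant), labels as a two-column TSV, volumes as NIfTI via nibabel,
configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .roi import RoiBetaMatrix
from .synthetic import SyntheticConfig, SyntheticDataset


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_deviance_plot(path, out_file) -> None:
    """Plot LOOCV binomial deviance against log10(lambda)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.log10(path.lambdas), path.deviances, marker=".", lw=1)
    ax.axvline(np.log10(path.selected_lambda), color="crimson", ls="--",
               label=f"selected $\\lambda$ = {path.selected_lambda:.4g}")
    ax.set_xlabel(r"$\log_{10}\,\lambda$")
    ax.set_ylabel("LOOCV binomial deviance")
    if path.family:
        ax.set_title(path.family)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_file, dpi=150)
    plt.close(fig)


def write_beta_matrix(matrix: RoiBetaMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.roi_names, columns=matrix.task_names)
    df.index.name = "roi"
    df.to_csv(path, sep="\t")


def read_beta_matrix(path, participant_id: str = "") -> RoiBetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RoiBetaMatrix(
        values=df.to_numpy(),
        roi_names=list(df.index),
        participant_id=participant_id or Path(path).stem,
        task_names=tuple(df.columns),
    )


def write_labels(participant_ids: list[str], labels, path) -> None:
    pd.DataFrame({"participant_id": participant_ids, "group": np.asarray(labels, int)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return list(df["participant_id"]), df["group"].to_numpy(dtype=int)


def save_volume(array: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array), affine=np.eye(4)), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_config(config: SyntheticConfig, path) -> None:
    data = {
        "schema": "taskpca-synthetic/1",
        "n_pos": config.n_pos,
        "n_neg": config.n_neg,
        "n_rois": config.n_rois,
        "n_tasks": config.n_tasks,
        "singular_values": [float(s) for s in config.singular_values],
        "effect_rois": [int(i) for i in config.effect_rois],
        "effect_size": config.effect_size,
        "jitter": config.jitter,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "voxel_mode": config.voxel_mode,
        "voxels_per_roi": config.voxels_per_roi,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path) -> SyntheticConfig:
    data = yaml.safe_load(Path(path).read_text())
    schema = data.pop("schema", None)
    if schema not in (None, "taskpca-synthetic/1"):
        raise ValueError(f"unknown config schema {schema!r}")
    if "singular_values" in data:
        data["singular_values"] = tuple(data["singular_values"])
    if "effect_rois" in data and data["effect_rois"] is not None:
        data["effect_rois"] = tuple(data["effect_rois"])
    return SyntheticConfig(**data)


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write a synthetic dataset: beta TSVs, labels, config, any volumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in dataset.beta_matrices:
        write_beta_matrix(m, out / f"beta_{m.participant_id}.tsv")
    write_labels(dataset.participant_ids, dataset.labels, out / "labels.tsv")
    write_config(dataset.truth, out / "config.yaml")
    if dataset.label_volume is not None:
        save_volume(dataset.label_volume, out / "atlas_labels.nii.gz")
    if dataset.volumes is not None:
        for pid, vols in zip(dataset.participant_ids, dataset.volumes):
            for task, vol in vols.items():
                save_volume(vol, out / f"contrast_{pid}_{task}.nii.gz")


def read_dataset_tables(data_dir) -> tuple[list[RoiBetaMatrix], np.ndarray]:
    """Load beta TSVs + labels written by :func:`write_dataset`."""
    data = Path(data_dir)
    ids, labels = read_labels(data / "labels.tsv")
    matrices = [read_beta_matrix(data / f"beta_{pid}.tsv", pid) for pid in ids]
    return matrices, labels
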