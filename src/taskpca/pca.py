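"""Per-participant PCA across task contrasts.

Each participant contributes a p x n matrix X of ROI mean beta values
(p ROIs as observations in rows, n = 3 task contrasts as variables in
columns). After centering each column by its mean over the p ROIs and
dividing the whole matrix by sqrt(n - 1), the singular value decomposition

    X' = U diag(s) V^T

yields ROI-space component vectors U (the "PC loadings" used downstream as
classification features), task-side coordinates V, and explained-variance
proportions s_k^2 / sum(s^2). Because each component vector is defined only
up to sign, a within-subject orientation convention plus a cross-subject
alignment step make loadings comparable across participants before they are
pooled into a feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .roi import RoiBetaMatrix
from .tables import FeatureTable


@dataclass
class SubjectPca:
    """One participant's decomposition of the ROI x task beta matrix.

    ``components`` is p x n with orthonormal columns (descending variance
    order); ``scores`` is the n x n task-side matrix V scaled by the singular
    values, so ``components @ scores.T`` reconstructs the centered, scaled
    input.
    """

    components: np.ndarray
    singular_values: np.ndarray
    explained_proportions: np.ndarray
    scores: np.ndarray
    roi_names: list[str]
    task_names: tuple[str, ...]
    participant_id: str = ""

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def component(self, pc_index: int) -> np.ndarray:
        """Component vector by 1-based index (PC1 = 1)."""
        if not 1 <= pc_index <= self.n_components:
            raise ValueError(f"pc_index must be in 1..{self.n_components}")
        return self.components[:, pc_index - 1]


def _orient_within_subject(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic per-subject sign: largest-|entry| loading made positive.
    U = U.copy()
    V = V.copy()
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, V


def centered_scaled(X: np.ndarray) -> np.ndarray:
    """Column-center X and divide by sqrt(n_columns - 1)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    return (X - X.mean(axis=0)) / np.sqrt(n - 1)


def subject_pca(X: RoiBetaMatrix | np.ndarray, participant_id: str | None = None) -> SubjectPca:
    """Decompose one participant's ROI x task matrix.

    Parameters
    ----------
    X
        A :class:`~taskpca.roi.RoiBetaMatrix` or a plain p x n array with
        p > n.

    Raises
    ------
    ValueError
        If the matrix has zero variance after centering (all-constant
        columns), or p <= n.
    """
    if isinstance(X, RoiBetaMatrix):
        values = X.values
        roi_names = X.roi_names
        task_names = X.task_names
        pid = X.participant_id if participant_id is None else participant_id
    else:
        values = np.asarray(X, dtype=float)
        roi_names = [f"roi-{i+1}" for i in range(values.shape[0])]
        task_names = tuple(f"task-{j+1}" for j in range(values.shape[1]))
        pid = participant_id or ""
    p, n = values.shape
    if p <= n:
        raise ValueError(f"need more ROIs than tasks (got {p} x {n})")
    if not np.all(np.isfinite(values)):
        raise ValueError("input matrix must be finite")
    Xc = centered_scaled(values)
    total = np.sum(Xc**2)
    if total <= 0:
        raise ValueError("degenerate input: zero variance after centering")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt.T
    U, V = _orient_within_subject(U, V)
    proportions = s**2 / np.sum(s**2)
    return SubjectPca(
        components=U,
        singular_values=s,
        explained_proportions=proportions,
        scores=V * s,  # columns scaled by singular values
        roi_names=list(roi_names),
        task_names=tuple(task_names),
        participant_id=pid,
    )


def align_component_signs(pcas: list[SubjectPca], pc_index: int) -> list[SubjectPca]:
    """Resolve the cross-subject sign ambiguity of one component.

    Each subject's component ``pc_index`` is first put in the deterministic
    within-subject orientation (largest-|entry| positive); the elementwise
    median of these oriented vectors serves as a reference direction, and any
    subject whose oriented vector has a negative inner product with it is
    flipped. The procedure is idempotent and never changes |loading|.
    """
    if not pcas:
        return []
    p = pcas[0].components.shape[0]
    for pca in pcas:
        if pca.components.shape[0] != p:
            raise ValueError("all subjects must share the ROI dimension")
    k = pc_index - 1
    if not 0 <= k < pcas[0].n_components:
        raise ValueError(f"pc_index must be in 1..{pcas[0].n_components}")

    def canonical_sign(v: np.ndarray) -> float:
        i = int(np.argmax(np.abs(v)))
        return -1.0 if v[i] < 0 else 1.0

    oriented = np.column_stack(
        [canonical_sign(pca.components[:, k]) * pca.components[:, k] for pca in pcas]
    )
    reference = np.median(oriented, axis=1)
    out = []
    for pca, vec in zip(pcas, oriented.T):
        flip = -1.0 if float(vec @ reference) < 0 else 1.0
        total = flip * canonical_sign(pca.components[:, k])
        if total < 0:
            components = pca.components.copy()
            scores = pca.scores.copy()
            components[:, k] = -components[:, k]
            scores[:, k] = -scores[:, k]
            out.append(replace(pca, components=components, scores=scores))
        else:
            out.append(pca)
    return out


def build_feature_matrix(
    pcas: list[SubjectPca], pc_index: int, labels: np.ndarray
) -> FeatureTable:
    """Pool one component across participants into a p x m feature table.

    Column j is participant j's component-``pc_index`` loading vector; sign
    alignment (:func:`align_component_signs`) should already have been
    applied.
    """
    if not pcas:
        raise ValueError("no subjects")
    p = pcas[0].components.shape[0]
    names = pcas[0].roi_names
    for pca in pcas:
        if pca.components.shape[0] != p:
            raise ValueError("all subjects must share the ROI dimension")
    values = np.column_stack([pca.component(pc_index) for pca in pcas])
    return FeatureTable(
        values=values,
        feature_names=list(names),
        labels=labels,
        family=f"PC{pc_index}",
        participant_ids=[pca.participant_id or f"sub-{j+1:02d}" for j, pca in enumerate(pcas)],
    )


def build_single_task_features(
    matrices: list[RoiBetaMatrix], task: str, labels: np.ndarray
) -> FeatureTable:
    """Pool one task's ROI beta column across participants (p x m)."""
    if not matrices:
        raise ValueError("no participants")
    names = matrices[0].roi_names
    for m in matrices:
        if m.roi_names != names:
            raise ValueError("matrices do not share ROI ordering")
    values = np.column_stack([m.task_column(task) for m in matrices])
    return FeatureTable(
        values=values,
        feature_names=list(names),
        labels=labels,
        family=task,
        participant_ids=[m.participant_id or f"sub-{j+1:02d}" for j, m in enumerate(matrices)],
    )


def summarize_explained_variance(
    pcas: list[SubjectPca], labels: np.ndarray, group_names: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-group, per-component mean / SD / SEM of explained variance (%).

    SD uses the sample convention (ddof = 1); SEM = SD / sqrt(group size).
    Each group needs at least 2 subjects.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(pcas):
        raise ValueError("labels length must match subject count")
    group_names = group_names or {1: "case", 0: "control"}
    props = np.vstack([pca.explained_proportions for pca in pcas]) * 100.0
    rows = []
    for g in sorted(set(labels), reverse=True):
        sel = props[labels == g]
        if sel.shape[0] < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects; SD undefined")
        mean = sel.mean(axis=0)
        sd = sel.std(axis=0, ddof=1)
        sem = sd / np.sqrt(sel.shape[0])
        for k in range(props.shape[1]):
            rows.append(
                {
                    "group": group_names.get(g, str(g)),
                    "n": sel.shape[0],
                    "pc": f"PC{k+1}",
                    "mean_percent": mean[k],
                    "sd": sd[k],
                    "sem": sem[k],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class VoxelPcaMaps:
    """Voxelwise component maps from group-mean contrast volumes."""

    maps: np.ndarray  # (n_components, *grid); NaN outside the mask
    explained_proportions: np.ndarray
    singular_values: np.ndarray
    mask: np.ndarray
    task_names: tuple[str, ...]


def voxel_pca(
    mean_contrast_volumes: dict[str, np.ndarray], brain_mask: np.ndarray
) -> VoxelPcaMaps:
    """Voxel-based analogue of :func:`subject_pca` on group-mean volumes.

    Voxels inside ``brain_mask`` are the observations, tasks the variables;
    emits one signed loading map per component (NaN outside the mask).
    """
    tasks = tuple(mean_contrast_volumes)
    if len(tasks) < 2:
        raise ValueError("need at least 2 task volumes")
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    grid = mask.shape
    cols = []
    for t in tasks:
        vol = np.asarray(mean_contrast_volumes[t], dtype=float)
        if vol.shape != grid:
            raise ValueError(f"volume for {t!r} not on the mask grid")
        cols.append(vol[mask])
    X = np.column_stack(cols)
    res = subject_pca(X)
    n_pc = res.n_components
    maps = np.full((n_pc, *grid), np.nan)
    for k in range(n_pc):
        maps[k][mask] = res.components[:, k]
    return VoxelPcaMaps(
        maps=maps,
        explained_proportions=res.explained_proportions,
        singular_values=res.singular_values,
        mask=mask,
        task_names=tasks,
    )
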