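"""ROI mean beta extraction with the positive-voxel threshold rule.

For each atlas region and task contrast, the region value is the mean of the
voxels whose beta exceeds 0.1 x the region's maximum beta. Because the
threshold is strictly positive whenever the maximum is, only positive voxels
contribute; a region whose maximum is <= 0 carries no usable signal and is
reported as 0 with a coverage flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import TASKS, AtlasLabels

THRESHOLD_FRACTION = 0.1


@dataclass
class RoiBetaMatrix:
    """One participant's ROIs x tasks matrix of mean beta values.

    Rows follow atlas order of ``roi_names``; columns follow the fixed task
    order (picture, sound, Stroop). ``coverage_flags[i]`` is set when no voxel
    of ROI i passed the threshold in at least one task.
    """

    values: np.ndarray
    roi_names: list[str]
    participant_id: str = ""
    coverage_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    task_names: tuple[str, ...] = TASKS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (ROIs x tasks)")
        p, n = self.values.shape
        if len(self.roi_names) != p:
            raise ValueError("roi_names length must match row count")
        if len(self.task_names) != n:
            raise ValueError("task_names length must match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("ROI mean beta values are nonnegative by construction")
        if self.coverage_flags is None:
            self.coverage_flags = np.zeros(p, dtype=bool)
        else:
            self.coverage_flags = np.asarray(self.coverage_flags, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, names: list[str]) -> "RoiBetaMatrix":
        """Restrict to the given ROI names (kept in the given order)."""
        index = {n: i for i, n in enumerate(self.roi_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise ValueError(f"ROIs not in matrix: {missing}")
        rows = [index[n] for n in names]
        return RoiBetaMatrix(
            values=self.values[rows],
            roi_names=list(names),
            participant_id=self.participant_id,
            coverage_flags=self.coverage_flags[rows],
            task_names=self.task_names,
        )

    def task_column(self, task: str) -> np.ndarray:
        if task not in self.task_names:
            raise ValueError(f"unknown task {task!r}; expected one of {self.task_names}")
        return self.values[:, self.task_names.index(task)]


def extract_roi_value(contrast_volume: np.ndarray, roi_mask: np.ndarray) -> tuple[float, bool]:
    """Mean of voxels strictly above 0.1 x the ROI maximum.

    Returns ``(value, uncovered)``. If the ROI maximum is <= 0 there are no
    positive voxels to average; the value is 0.0 and the coverage flag is set.

    Raises
    ------
    ValueError
        If the mask selects no voxels.
    """
    vox = np.asarray(contrast_volume)[np.asarray(roi_mask, dtype=bool)]
    if vox.size == 0:
        raise ValueError("empty ROI mask")
    peak = vox.max()
    if peak <= 0:
        return 0.0, True
    survivors = vox[vox > THRESHOLD_FRACTION * peak]
    return float(survivors.mean()), False


def extract_roibvals(
    volumes: dict[str, np.ndarray],
    atlas: AtlasLabels,
    participant_id: str = "",
    tasks: tuple[str, ...] = TASKS,
) -> RoiBetaMatrix:
    """Extract the per-ROI per-task mean beta matrix for one participant.

    ``volumes`` maps task name -> contrast volume on the atlas grid. All atlas
    labels are extracted (exclusion happens later via :func:`filter_rois` /
    :meth:`RoiBetaMatrix.subset`); an ROI absent from the label volume is
    flagged uncovered.
    """
    missing = [t for t in tasks if t not in volumes]
    if missing:
        raise ValueError(f"missing task volumes: {missing}")
    grid = atlas.label_volume.shape
    for t in tasks:
        if np.asarray(volumes[t]).shape != grid:
            raise ValueError(
                f"volume for task {t!r} has shape {np.asarray(volumes[t]).shape}, "
                f"label volume has {grid}"
            )
    labels = atlas.ordered_labels
    p = len(labels)
    values = np.zeros((p, len(tasks)))
    flags = np.zeros(p, dtype=bool)
    for i, label in enumerate(labels):
        mask = atlas.mask(label)
        if not mask.any():
            flags[i] = True
            continue
        for j, t in enumerate(tasks):
            value, uncovered = extract_roi_value(volumes[t], mask)
            values[i, j] = value
            flags[i] |= uncovered
    return RoiBetaMatrix(
        values=values,
        roi_names=atlas.ordered_names,
        participant_id=participant_id,
        coverage_flags=flags,
        task_names=tasks,
    )


def filter_rois(
    matrices: list[RoiBetaMatrix],
    atlas: AtlasLabels,
    mode: str = "list",
) -> list[str]:
    """Names of the ROIs retained for analysis, in atlas order.

    mode="list"
        Drop the atlas's fixed exclusion list (the default 12-region list,
        retaining 78 of 90).
    mode="coverage"
        Drop any ROI whose coverage flag is set for any participant.
    """
    if mode == "list":
        return atlas.retained_names()
    if mode == "coverage":
        if not matrices:
            raise ValueError("coverage mode needs at least one matrix")
        names = matrices[0].roi_names
        for m in matrices[1:]:
            if m.roi_names != names:
                raise ValueError("matrices do not share ROI ordering")
        flagged = np.zeros(len(names), dtype=bool)
        for m in matrices:
            flagged |= m.coverage_flags
        return [n for n, bad in zip(names, flagged) if not bad]
    raise ValueError(f"unknown mode {mode!r}; expected 'list' or 'coverage'")
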