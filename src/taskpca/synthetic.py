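"""Two-group synthetic multitask ROI beta datasets.

Each participant's ROIs x tasks beta matrix is built from the low-rank
structure the analysis assumes:

    X = U_s diag(s) V^T + noise,  then shifted so every entry is positive

where U_s is the participant's ROI-space loading pattern (the group pattern
plus a small per-subject perturbation, re-orthonormalized), s are the shared
singular values, and V is a fixed orthonormal task-mixing matrix. The two
group patterns share components 1 and 3; the patient group's component-2
pattern is perturbed at a small set of "effect" ROIs, emulating a disease
signature detectable through component-2 loadings. Group patterns have zero
column means, so the positivity shift and column centering downstream leave
the planted structure recoverable exactly at zero noise.

Default dimensions mirror the emulated study: 19 patients vs 21 controls,
78 ROIs, 3 task contrasts, singular-value shares 70/20/10 percent, and six
effect ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AAL90_NAMES, DEFAULT_EXCLUDED, TASKS, AtlasLabels
from .roi import RoiBetaMatrix

#: default effect regions: the AAL names of the six regions whose
#: component-2 loadings separate the groups in the emulated study
DEFAULT_EFFECT_ROI_NAMES: tuple[str, ...] = (
    "Frontal_Inf_Orb_L",
    "Frontal_Inf_Orb_R",
    "Calcarine_R",
    "Lingual_R",
    "Occipital_Inf_L",
    "Temporal_Inf_L",
)

_SV_SHARES = (0.70, 0.20, 0.10)
_SV_SCALE = 3.0
_MIN_ENTRY = 0.01  # positivity shift floor


def _default_roi_names(n_rois: int) -> list[str]:
    if n_rois == 78:
        excluded = set(DEFAULT_EXCLUDED)
        return [n for k, n in sorted(AAL90_NAMES.items()) if n not in excluded]
    return [f"ROI_{i+1:03d}" for i in range(n_rois)]


def _zero_mean_orthonormal(A: np.ndarray) -> np.ndarray:
    """Column-center then QR-orthonormalize; deterministic signs."""
    A = A - A.mean(axis=0)
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def task_mixing_matrix(n_tasks: int) -> np.ndarray:
    """The fixed orthonormal task-side mixing matrix V (seed-independent)."""
    rng = np.random.default_rng(20210430)
    Q, R = np.linalg.qr(rng.normal(size=(n_tasks, n_tasks)))
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the emulated study conditions.

    ``effect_size`` is the magnitude of the perturbation added to the
    patient group's component-2 pattern at ``effect_rois`` before
    re-orthonormalization (loading patterns are unit-norm, so 0.5 is a
    strong, easily recoverable effect). ``jitter`` scales the per-subject
    Gaussian perturbation of the loading patterns; ``noise_sd`` is the SD of
    the independent Gaussian noise added to every matrix entry.
    """

    n_pos: int = 19
    n_neg: int = 21
    n_rois: int = 78
    n_tasks: int = 3
    singular_values: tuple[float, ...] = tuple(
        _SV_SCALE * np.sqrt(s) for s in _SV_SHARES
    )
    group_loading_patterns: dict[int, np.ndarray] | None = None
    effect_rois: tuple[int, ...] | None = None  # 0-based indices; None -> default 6
    effect_size: float = 0.5
    jitter: float = 0.05
    noise_sd: float = 0.05
    seed: int = 0
    voxel_mode: bool = False
    voxels_per_roi: int = 8
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("each group needs at least one participant")
        if not self.n_rois >= self.n_tasks >= 2:
            raise ValueError("need n_rois >= n_tasks >= 2")
        if len(self.singular_values) != self.n_tasks:
            raise ValueError("singular_values must have one entry per task")
        if any(s < 0 for s in self.singular_values):
            raise ValueError("singular values must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        if not self.roi_names:
            self.roi_names = _default_roi_names(self.n_rois)
        elif len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length must equal n_rois")
        if self.effect_rois is None:
            if self.n_rois == 78:
                self.effect_rois = tuple(
                    self.roi_names.index(n) for n in DEFAULT_EFFECT_ROI_NAMES
                )
            else:
                rng = np.random.default_rng(self.seed)
                k = min(6, self.n_rois)
                self.effect_rois = tuple(
                    sorted(rng.choice(self.n_rois, size=k, replace=False).tolist())
                )
        if any(not 0 <= i < self.n_rois for i in self.effect_rois):
            raise ValueError("effect_rois indices out of range")
        if self.voxels_per_roi < 3:
            raise ValueError("need at least 3 voxels per ROI")
        if self.group_loading_patterns is not None:
            for g, U in self.group_loading_patterns.items():
                U = np.asarray(U, dtype=float)
                if U.shape != (self.n_rois, self.n_tasks):
                    raise ValueError(f"group {g} pattern has wrong shape")
                if not np.allclose(U.T @ U, np.eye(self.n_tasks), atol=1e-8):
                    raise ValueError(f"group {g} pattern not orthonormal to 1e-8")

    @property
    def n_subjects(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def effect_roi_names(self) -> list[str]:
        return [self.roi_names[i] for i in self.effect_rois]


@dataclass
class SyntheticDataset:
    beta_matrices: list[RoiBetaMatrix]
    labels: np.ndarray
    truth: SyntheticConfig
    group_patterns: dict[int, np.ndarray]
    label_volume: np.ndarray | None = None
    volumes: list[dict[str, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.beta_matrices) != len(self.labels):
            raise ValueError("one label per beta matrix required")

    @property
    def participant_ids(self) -> list[str]:
        return [m.participant_id for m in self.beta_matrices]


def make_group_patterns(config: SyntheticConfig) -> dict[int, np.ndarray]:
    """Unit-norm, mutually orthogonal, zero-column-mean loading patterns.

    Group 0 (controls) gets the base pattern; group 1 (patients) shares
    components 1 and 3 up to re-orthonormalization, with component 2
    perturbed by ``effect_size`` at the effect ROIs.
    """
    if config.group_loading_patterns is not None:
        return {g: np.asarray(U, float) for g, U in config.group_loading_patterns.items()}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    base = _zero_mean_orthonormal(rng.normal(size=(config.n_rois, config.n_tasks)))
    delta = np.zeros(config.n_rois)
    for j, i in enumerate(config.effect_rois):
        delta[i] = 1.0 if j % 2 == 0 else -1.0
    norm = np.linalg.norm(delta)
    if norm > 0:
        delta /= norm
    perturbed = base.copy()
    if config.n_tasks >= 2:
        perturbed[:, 1] = perturbed[:, 1] + config.effect_size * delta
    patient = _zero_mean_orthonormal(perturbed)
    return {0: base, 1: patient}


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full two-group dataset (identical seed => identical data)."""
    patterns = make_group_patterns(config)
    V = task_mixing_matrix(config.n_tasks)
    s = np.asarray(config.singular_values, dtype=float)
    labels = np.array([1] * config.n_pos + [0] * config.n_neg)
    ids = [f"PI-{i+1:02d}" for i in range(config.n_pos)] + [
        f"HC-{i+1:02d}" for i in range(config.n_neg)
    ]
    matrices = []
    for j, (g, pid) in enumerate(zip(labels, ids)):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, j]))
        U_g = patterns[int(g)]
        if config.jitter > 0:
            G = rng.normal(size=U_g.shape)
            U_s = _zero_mean_orthonormal(U_g + config.jitter * G)
        else:
            rng.normal(size=U_g.shape)  # keep the stream layout stable
            U_s = U_g
        X = U_s @ np.diag(s) @ V.T
        if config.noise_sd > 0:
            X = X + config.noise_sd * rng.normal(size=X.shape)
        lo = X.min()
        if lo < _MIN_ENTRY:
            X = X + (_MIN_ENTRY - lo)
        matrices.append(
            RoiBetaMatrix(
                values=X,
                roi_names=list(config.roi_names),
                participant_id=pid,
                task_names=TASKS if config.n_tasks == 3 else tuple(
                    f"task-{k+1}" for k in range(config.n_tasks)
                ),
            )
        )
    dataset = SyntheticDataset(
        beta_matrices=matrices, labels=labels, truth=config, group_patterns=patterns
    )
    if config.voxel_mode:
        label_volume = None
        volumes = []
        for mat in matrices:
            lv, vols = generate_volumes(config, mat)
            label_volume = lv
            volumes.append(vols)
        dataset.label_volume = label_volume
        dataset.volumes = volumes
    return dataset


def synthetic_atlas(config: SyntheticConfig) -> AtlasLabels:
    """The label volume + naming matching :func:`generate_volumes` output."""
    label_volume, _ = _volume_layout(config)
    if config.n_rois == 78 and set(config.roi_names) <= set(AAL90_NAMES.values()):
        return AtlasLabels(label_volume=label_volume)
    names = {i + 1: n for i, n in enumerate(config.roi_names)}
    return AtlasLabels(label_volume=label_volume, label_names=names, excluded_names=())


def _volume_layout(config: SyntheticConfig) -> tuple[np.ndarray, dict[str, int]]:
    """Grid of shape (n_labels, 1, voxels_per_roi); one label per row."""
    if config.n_rois == 78 and set(config.roi_names) <= set(AAL90_NAMES.values()):
        names = dict(AAL90_NAMES)  # full 90-label atlas incl. excluded regions
    else:
        names = {i + 1: n for i, n in enumerate(config.roi_names)}
    k = config.voxels_per_roi
    labels = sorted(names)
    vol = np.zeros((len(labels), 1, k), dtype=np.int32)
    for row, label in enumerate(labels):
        vol[row, 0, :] = label
    name_to_label = {n: lab for lab, n in names.items()}
    return vol, name_to_label


def _roi_voxels(b: float, k: int) -> np.ndarray:
    """Voxels whose supra-threshold (0.1 x max) mean is exactly b.

    Plants one sub-threshold voxel (0.05 b) and, when room allows, one
    negative voxel (-b) to exercise the extraction filter.
    """
    if b <= 0:
        return np.full(k, -1.0)
    vox = np.full(k, b)
    vox[0] = 1.25 * b
    vox[1] = 0.75 * b
    vox[2] = 0.05 * b  # below the 0.125 b threshold
    if k >= 4:
        vox[3] = -b
    return vox


def generate_volumes(
    config: SyntheticConfig, beta: RoiBetaMatrix
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Labelled voxel volumes whose extraction recovers ``beta`` exactly.

    Returns ``(label_volume, {task: beta_volume})``. Atlas labels not in
    ``beta`` (the excluded regions) receive only negative voxels, so ROI
    extraction flags them as uncovered.
    """
    if config.voxels_per_roi < 3:
        raise ValueError("need at least 3 voxels per ROI")
    label_volume, name_to_label = _volume_layout(config)
    labels = sorted(name_to_label.values())
    row_of_label = {lab: row for row, lab in enumerate(labels)}
    k = config.voxels_per_roi
    volumes: dict[str, np.ndarray] = {}
    for j, task in enumerate(beta.task_names):
        vol = np.full(label_volume.shape, -1.0)
        for i, name in enumerate(beta.roi_names):
            row = row_of_label[name_to_label[name]]
            vol[row, 0, :] = _roi_voxels(float(beta.values[i, j]), k)
        volumes[task] = vol
    return label_volume, volumes
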