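"""AAL-90 cerebral parcellation bookkeeping.

The Automated Anatomical Labeling atlas assigns integer labels 1..90 to the
cerebral regions (45 left/right pairs, interleaved L, R in standard order).
Twelve regions with poor task coverage are excluded from analysis by default,
leaving the 78 regions the classification pipeline operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 45 left/right pairs in standard AAL order (label 2k-1 = left, 2k = right).
_AAL_STEMS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

#: label -> region name for the 90 cerebral AAL regions
AAL90_NAMES: dict[int, str] = {
    2 * k + 1 + side: f"{stem}_{'LR'[side]}"
    for k, stem in enumerate(_AAL_STEMS)
    for side in (0, 1)
}

#: the 12 regions dropped for insufficient coverage, leaving 78
DEFAULT_EXCLUDED: tuple[str, ...] = (
    "Olfactory_L", "Olfactory_R",
    "Amygdala_L", "Amygdala_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Pallidum_L", "Pallidum_R",
)

#: fixed task-contrast column order used throughout
TASKS: tuple[str, ...] = ("picture", "sound", "Stroop")


@dataclass
class AtlasLabels:
    """An integer label volume plus its label -> name mapping.

    Parameters
    ----------
    label_volume
        3-D integer array; 0 is background, positive values are region labels.
    label_names
        Mapping from label integer to region name.
    excluded_names
        Ordered names excluded from analysis (default: the 12-region list).
    """

    label_volume: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: dict(AAL90_NAMES))
    excluded_names: tuple[str, ...] = DEFAULT_EXCLUDED

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label volume must be an integer array")
        if self.label_volume.min() < 0:
            raise ValueError("labels must be nonnegative (0 = background)")
        unknown = set(self.excluded_names) - set(self.label_names.values())
        if unknown:
            raise ValueError(f"excluded names not in atlas: {sorted(unknown)}")

    @property
    def ordered_labels(self) -> list[int]:
        """All labels in ascending (atlas) order."""
        return sorted(self.label_names)

    @property
    def ordered_names(self) -> list[str]:
        return [self.label_names[k] for k in self.ordered_labels]

    def retained_names(self) -> list[str]:
        """Atlas-order names minus the exclusion list."""
        dropped = set(self.excluded_names)
        return [n for n in self.ordered_names if n not in dropped]

    def mask(self, label: int) -> np.ndarray:
        return self.label_volume == label


def read_label_names(path) -> dict[int, str]:
    """Read a two-column delimited file (label, name) into a mapping."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, name = line.split(None, 1)
            out[int(label)] = name.strip()
    return out
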