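"""Cross-participant feature tables (features x participants)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureTable:
    """A p x m matrix of one feature family plus binary group labels.

    Rows are features (ROIs), columns are participants. Labels use the
    patient-positive convention (case = 1, control = 0). ``family`` tags the
    feature origin: one of PC1/PC2/PC3 (component loadings) or
    picture/sound/Stroop (single-task ROI beta values).
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    family: str = ""
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        p, m = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal row count")
        if self.labels.shape != (m,):
            raise ValueError("labels length must equal participant count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(set(self.labels)) < 2:
            raise ValueError("both classes must be present")
        if not self.participant_ids:
            self.participant_ids = [f"sub-{i+1:02d}" for i in range(m)]
        elif len(self.participant_ids) != m:
            raise ValueError("participant_ids length must equal participant count")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_participants(self) -> int:
        return self.values.shape[1]

    def design(self) -> np.ndarray:
        """Participants x features design matrix (the transpose of `values`)."""
        return self.values.T.copy()

    def subset_features(self, names: list[str]) -> "FeatureTable":
        index = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise ValueError(f"unknown features: {missing}")
        rows = [index[n] for n in names]
        return FeatureTable(
            values=self.values[rows],
            feature_names=list(names),
            labels=self.labels,
            family=self.family,
            participant_ids=self.participant_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_names, columns=self.participant_ids
        )

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "feature"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, labels: np.ndarray, family: str = "") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(),
            feature_names=list(df.index),
            labels=labels,
            family=family,
            participant_ids=list(df.columns),
        )
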