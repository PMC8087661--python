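"""RBF soft-margin SVM classification under leave-one-out cross-validation.

The classifier is the standard soft-margin SVM with Gaussian kernel
exp(-gamma * ||x_i - x_j||^2) and misclassification cost C. Both
hyperparameters are chosen by grid search over [0.1, 10] (log-equispaced),
scoring each pair by the pooled leave-one-out accuracy; ties break toward
the smallest C then the smallest gamma (maximum regularization). The pooled
held-out predictions of the winning pair feed a single confusion matrix from
which the five performance metrics are computed.

`compare_feature_sets` runs the full select -> classify -> score chain for
several feature families (component loadings and single-task beta values)
with identical folds, reproducing the study's family comparison. By default
feature selection runs once on the full sample before the SVM loop —
faithful to the original analysis but leaking label information across
folds; `nested=True` re-runs selection inside every fold for an honest
generalization estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .lasso import LassoPath, select_lambda_loocv
from .metrics import MetricsReport, compute_metrics, confusion_from_predictions
from .tables import FeatureTable

GRID_MIN = 0.1
GRID_MAX = 10.0
GRID_RESOLUTION = 20


def default_grid(resolution: int = GRID_RESOLUTION) -> np.ndarray:
    return np.geomspace(GRID_MIN, GRID_MAX, resolution)


@dataclass
class SvmConfig:
    """Hyperparameter grids for the RBF SVM search."""

    C_grid: np.ndarray = field(default_factory=default_grid)
    gamma_grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.C_grid = np.sort(np.asarray(self.C_grid, dtype=float))
        self.gamma_grid = np.sort(np.asarray(self.gamma_grid, dtype=float))
        for name, grid in (("C_grid", self.C_grid), ("gamma_grid", self.gamma_grid)):
            if grid.size == 0:
                raise ValueError(f"{name} is empty")
            if grid.min() < GRID_MIN - 1e-12 or grid.max() > GRID_MAX + 1e-12:
                raise ValueError(f"{name} values must lie in [{GRID_MIN}, {GRID_MAX}]")


@dataclass
class SvmResult:
    best_C: float
    best_gamma: float
    accuracy: float
    predictions: np.ndarray  # pooled LOOCV predictions at the best pair
    accuracy_grid: np.ndarray  # (len(C_grid), len(gamma_grid))


def _loocv_predictions_rbf(
    K: np.ndarray, y: np.ndarray, C: float
) -> np.ndarray:
    """Pooled LOOCV predictions for a fixed precomputed kernel and C."""
    m = len(y)
    preds = np.empty(m, dtype=int)
    idx = np.arange(m)
    for i in range(m):
        train = idx != i
        clf = SVC(C=C, kernel="precomputed")
        clf.fit(K[np.ix_(train, train)], y[train])
        preds[i] = int(clf.predict(K[np.ix_([i], train)])[0])
    return preds


def svm_grid_search_loocv(
    table: FeatureTable, config: SvmConfig | None = None, seed: int = 0
) -> SvmResult:
    """Grid-search (C, gamma) by pooled LOOCV accuracy.

    The fit is deterministic for binary SVC; ``seed`` is accepted for
    interface uniformity. Requires at least 4 participants with both classes
    having >= 2 members (so no training fold is single-class).
    """
    config = config or SvmConfig()
    X = table.design()
    y = table.labels
    m = len(y)
    if m < 4:
        raise ValueError("LOOCV grid search needs at least 4 participants")
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("each class needs at least 2 participants")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    n_C, n_g = len(config.C_grid), len(config.gamma_grid)
    preds_all = np.empty((n_C, n_g, m), dtype=int)
    idx = np.arange(m)
    for gj, gamma in enumerate(config.gamma_grid):
        K = np.exp(-gamma * d2)
        for i in range(m):
            train = idx != i
            K_train = K[np.ix_(train, train)]
            K_test = K[np.ix_([i], train)]
            y_train = y[train]
            for ci, C in enumerate(config.C_grid):
                clf = SVC(C=C, kernel="precomputed")
                clf.fit(K_train, y_train)
                preds_all[ci, gj, i] = int(clf.predict(K_test)[0])
    acc_grid = (preds_all == y).mean(axis=2)
    # tie-break: smallest C, then smallest gamma
    best = (-1.0, 0, 0)
    for ci in range(n_C):
        for gj in range(n_g):
            if acc_grid[ci, gj] > best[0] + 1e-12:
                best = (float(acc_grid[ci, gj]), ci, gj)
    acc, ci, gj = best
    return SvmResult(
        best_C=float(config.C_grid[ci]),
        best_gamma=float(config.gamma_grid[gj]),
        accuracy=acc,
        predictions=preds_all[ci, gj].copy(),
        accuracy_grid=acc_grid,
    )


@dataclass
class FamilyResult:
    """Selection + classification outcome for one feature family."""

    family: str
    lasso_path: LassoPath | None
    selected: list[str]
    svm: SvmResult | None
    metrics: MetricsReport | None


def classify_family(
    table: FeatureTable,
    config: SvmConfig | None = None,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    nested: bool = False,
) -> FamilyResult:
    """Feature selection then SVM classification for one feature table."""
    config = config or SvmConfig()
    if not nested:
        path = select_lambda_loocv(table, lambdas)
        selected = path.selected_features
        if not selected:
            return FamilyResult(table.family, path, [], None, None)
        sub = table.subset_features(selected)
        svm = svm_grid_search_loocv(sub, config, seed)
        cm = confusion_from_predictions(svm.predictions, table.labels)
        return FamilyResult(table.family, path, selected, svm, compute_metrics(cm))

    # nested: repeat selection + hyperparameter search inside every fold
    m = table.n_participants
    preds = np.empty(m, dtype=int)
    for i in range(m):
        keep = [j for j in range(m) if j != i]
        inner = FeatureTable(
            values=table.values[:, keep],
            feature_names=table.feature_names,
            labels=table.labels[keep],
            family=table.family,
            participant_ids=[table.participant_ids[j] for j in keep],
        )
        path = select_lambda_loocv(inner, lambdas)
        selected = path.selected_features
        if not selected:
            # null model: predict the training-fold majority class
            preds[i] = int(np.mean(inner.labels) >= 0.5)
            continue
        sub = inner.subset_features(selected)
        svm = svm_grid_search_loocv(sub, config, seed)
        rows = [table.feature_names.index(n) for n in selected]
        clf = SVC(C=svm.best_C, gamma=svm.best_gamma, kernel="rbf")
        clf.fit(sub.design(), sub.labels)
        preds[i] = int(clf.predict(table.values[rows, i][None, :])[0])
    cm = confusion_from_predictions(preds, table.labels)
    return FamilyResult(table.family, None, [], None, compute_metrics(cm))


def compare_feature_sets(
    tables: dict[str, FeatureTable],
    config: SvmConfig | None = None,
    seed: int = 0,
    nested: bool = False,
) -> dict[str, FamilyResult]:
    """Run select -> classify -> score per family with identical folds."""
    if not tables:
        raise ValueError("no feature tables")
    families = list(tables)
    ref = tables[families[0]]
    for name in families[1:]:
        t = tables[name]
        if t.participant_ids != ref.participant_ids or not np.array_equal(
            t.labels, ref.labels
        ):
            raise ValueError("feature tables must share participants and labels")
    return {
        name: classify_family(tables[name], config, seed, nested=nested)
        for name in families
    }
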