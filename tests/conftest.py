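import numpy as np
import pytest

from taskpca import SyntheticConfig, generate_dataset
from taskpca.tables import FeatureTable


@pytest.fixture(scope="session")
def default_dataset():
    """Study-scale dataset at the generator defaults (19 vs 21, 78 x 3)."""
    return generate_dataset(SyntheticConfig(seed=2024))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap dataset for plumbing tests (12 subjects, 12 ROIs)."""
    config = SyntheticConfig(n_pos=6, n_neg=6, n_rois=12, n_tasks=3, seed=11)
    return generate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_feature_table(rng, p=10, m=16, family="") -> FeatureTable:
    values = rng.normal(size=(p, m))
    labels = np.zeros(m, dtype=int)
    labels[: m // 2] = 1
    return FeatureTable(
        values=values,
        feature_names=[f"f{i}" for i in range(p)],
        labels=labels,
        family=family,
    )
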