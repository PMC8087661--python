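import numpy as np
import pytest

from taskpca import (
    RoiBetaMatrix,
    SyntheticConfig,
    align_component_signs,
    build_feature_matrix,
    build_single_task_features,
    generate_dataset,
    subject_pca,
    summarize_explained_variance,
    voxel_pca,
)
from taskpca.pca import centered_scaled
from taskpca.synthetic import task_mixing_matrix


def eigen_oracle(X):
    """Brute-force oracle: eigendecompose the 3x3 Gram matrix of the
    centered, scaled input and lift the eigenvectors back to ROI space."""
    Xc = centered_scaled(X)
    evals, V = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(evals)[::-1]
    evals, V = evals[order], V[:, order]
    evals = np.maximum(evals, 0)
    U = Xc @ V / np.sqrt(evals)
    return U, evals / evals.sum()


def test_rank_one_matrix_explains_everything(rng):
    v = rng.normal(size=10)
    X = np.column_stack([v + 1.0, v + 2.0, v - 0.5])  # equal after centering
    res = subject_pca(X)
    np.testing.assert_allclose(res.explained_proportions, [1, 0, 0], atol=1e-12)


def test_orthogonal_columns_closed_form(rng):
    """Centered columns orthogonal with norms 3, 2, 1 give proportions
    9/14, 4/14, 1/14 (eigenvalues are the squared norms)."""
    A = rng.normal(size=(12, 3))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    X = np.column_stack([3 * Q[:, 0], 2 * Q[:, 1], 1 * Q[:, 2]])
    res = subject_pca(X)
    np.testing.assert_allclose(
        res.explained_proportions, np.array([9, 4, 1]) / 14, atol=1e-12
    )


def test_pca_agrees_with_eigen_oracle_on_100_seeded_matrices():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(78, 3)) + 0.5
        res = subject_pca(X)
        U_ref, props_ref = eigen_oracle(X)
        np.testing.assert_allclose(res.explained_proportions, props_ref, atol=1e-10)
        for k in range(3):
            dev = min(
                np.abs(res.components[:, k] - U_ref[:, k]).max(),
                np.abs(res.components[:, k] + U_ref[:, k]).max(),
            )
            assert dev < 1e-10


def test_structural_invariants(rng):
    X = rng.normal(size=(30, 3))
    res = subject_pca(X)
    np.testing.assert_allclose(
        res.components.T @ res.components, np.eye(3), atol=1e-8
    )
    assert np.all(np.diff(res.singular_values) <= 1e-12)
    np.testing.assert_allclose(res.explained_proportions.sum(), 1.0, atol=1e-10)
    # reconstruction: U diag(s) V^T = U scores^T equals the centered input
    np.testing.assert_allclose(
        res.components @ res.scores.T, centered_scaled(X), atol=1e-8
    )
    # proportions invariant to positive rescaling
    res2 = subject_pca(7.3 * X)
    np.testing.assert_allclose(
        res.explained_proportions, res2.explained_proportions, atol=1e-12
    )


def test_constant_matrix_is_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        subject_pca(np.ones((10, 3)))


def test_sign_alignment_flips_the_odd_subject_out(rng):
    X = rng.normal(size=(20, 3))
    pcas = [subject_pca(X + 0.01 * np.random.default_rng(s).normal(size=(20, 3)))
            for s in range(5)]
    # negate one subject's component 2 by hand
    import dataclasses
    flipped = dataclasses.replace(
        pcas[2],
        components=pcas[2].components * np.array([1, -1, 1]),
        scores=pcas[2].scores * np.array([1, -1, 1]),
    )
    mutated = pcas[:2] + [flipped] + pcas[3:]
    aligned = align_component_signs(mutated, 2)
    ref = np.median(np.column_stack([p.components[:, 1] for p in pcas]), axis=1)
    for p in aligned:
        assert p.components[:, 1] @ ref >= 0
    # |loading| never changes
    for before, after in zip(mutated, aligned):
        np.testing.assert_allclose(
            np.abs(before.components), np.abs(after.components), atol=1e-15
        )
    # idempotence: applying twice equals applying once
    again = align_component_signs(aligned, 2)
    for a, b in zip(aligned, again):
        np.testing.assert_array_equal(a.components, b.components)


def test_feature_matrix_assembly(small_dataset):
    pcas = [subject_pca(m) for m in small_dataset.beta_matrices]
    labels = small_dataset.labels
    aligned = align_component_signs(pcas, 2)
    table = build_feature_matrix(aligned, 2, labels)
    assert table.values.shape == (12, 12)
    assert table.family == "PC2"
    np.testing.assert_array_equal(table.values[:, 3], aligned[3].component(2))
    # permuting subjects permutes columns and labels consistently
    perm = np.random.default_rng(0).permutation(12)
    table_p = build_feature_matrix([aligned[i] for i in perm], 2, labels[perm])
    np.testing.assert_array_equal(table_p.values, table.values[:, perm])
    np.testing.assert_array_equal(table_p.labels, table.labels[perm])


def test_single_task_features_are_a_projection(small_dataset):
    table = build_single_task_features(
        small_dataset.beta_matrices, "sound", small_dataset.labels
    )
    assert table.family == "sound"
    for j, m in enumerate(small_dataset.beta_matrices):
        np.testing.assert_array_equal(table.values[:, j], m.values[:, 1])
    with pytest.raises(ValueError, match="unknown task"):
        build_single_task_features(small_dataset.beta_matrices, "rest", small_dataset.labels)


def test_zero_noise_group_means_match_mixed_patterns():
    """At zero noise, the column-centered group mean of a task's features
    equals the centered group pattern mixed by V and the singular values."""
    config = SyntheticConfig(noise_sd=0.0, jitter=0.0, seed=13)
    ds = generate_dataset(config)
    V = task_mixing_matrix(3)
    s = np.asarray(config.singular_values)
    table = build_single_task_features(ds.beta_matrices, "picture", ds.labels)
    j = 0  # picture column
    for g in (0, 1):
        grp = table.values[:, ds.labels == g].mean(axis=1)
        expected = ds.group_patterns[g] @ np.diag(s) @ V.T[:, j]
        np.testing.assert_allclose(
            grp - grp.mean(), expected - expected.mean(), atol=1e-10
        )


def test_explained_variance_summary(default_dataset):
    pcas = [subject_pca(m) for m in default_dataset.beta_matrices]
    df = summarize_explained_variance(pcas, default_dataset.labels,
                                      group_names={1: "PI", 0: "HC"})
    assert set(df["group"]) == {"PI", "HC"}
    for _, grp in df.groupby("group"):
        assert grp["mean_percent"].sum() == pytest.approx(100, abs=0.1)
        np.testing.assert_allclose(
            grp["sem"], grp["sd"] / np.sqrt(grp["n"]), atol=1e-10
        )
    # identical subjects: SD exactly 0
    same = [pcas[0]] * 4
    df0 = summarize_explained_variance(same, np.array([1, 1, 0, 0]))
    assert (df0["sd"] == 0).all()
    with pytest.raises(ValueError, match="fewer than 2"):
        summarize_explained_variance(pcas[:3], np.array([1, 1, 0]))


def test_voxel_pca_toy_patterns(rng):
    grid = (4, 4, 4)
    mask = np.ones(grid, dtype=bool)
    mask[0, 0, 0] = False
    # planted anticorrelated two-region pattern across tasks
    base = np.zeros(grid)
    base[:2] = 1.0
    base[2:] = -1.0
    vols = {"picture": base + 0.1, "sound": -base, "Stroop": 0.5 * base - 0.2}
    res = voxel_pca(vols, mask)
    pc1 = res.maps[0]
    assert np.isnan(pc1[0, 0, 0])  # masked voxels absent
    region_a = pc1[:2][mask[:2]]
    region_b = pc1[2:][mask[2:]]
    assert np.sign(region_a.mean()) != np.sign(region_b.mean())
    # identical task volumes: first component explains everything
    v = rng.normal(size=grid)
    res2 = voxel_pca({"picture": v, "sound": v, "Stroop": v}, mask)
    assert res2.explained_proportions[0] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="at least 2"):
        voxel_pca({"picture": v}, mask)
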