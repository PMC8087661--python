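import numpy as np
import pytest
from scipy.optimize import minimize

from taskpca import (
    binomial_deviance,
    lasso_logistic_path,
    make_lambda_grid,
    select_lambda_loocv,
    selected_features,
)
from taskpca.lasso import _standardize
from taskpca.tables import FeatureTable

from conftest import random_feature_table


def penalized_objective(table, lam, beta_orig, intercept_orig):
    """The penalized binomial objective in the standardized parametrization."""
    Xs, mu, sd = _standardize(table.design())
    y = table.labels.astype(float)
    beta_std = beta_orig * sd
    b0 = intercept_orig + beta_orig @ mu
    eta = b0 + Xs @ beta_std
    return float(
        np.sum(np.logaddexp(0, eta) - y * eta) / len(y)
        + lam * np.abs(beta_std).sum()
    )


def lbfgs_oracle(table, lam):
    """Direct minimization of the penalized binomial objective via the
    split-variable (beta = b+ - b-) smooth reformulation. Returns the
    original-scale coefficients and the achieved objective value."""
    Xs, mu, sd = _standardize(table.design())
    y = table.labels.astype(float)
    m, p = Xs.shape

    def objective(z):
        b0, bp, bn = z[0], z[1 : 1 + p], z[1 + p :]
        eta = b0 + Xs @ (bp - bn)
        return np.sum(np.logaddexp(0, eta) - y * eta) / m + lam * np.sum(bp + bn)

    res = minimize(
        objective,
        np.zeros(1 + 2 * p),
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0, None)] * (2 * p),
        options=dict(maxiter=200000, ftol=1e-17, gtol=1e-13),
    )
    beta_std = res.x[1 : 1 + p] - res.x[1 + p :]
    b0 = res.x[0]
    fun = float(res.fun)

    # Newton polish on the support found by L-BFGS-B: the objective is
    # smooth once the active set and signs are fixed, so a few Newton steps
    # reach machine precision.
    support = np.flatnonzero(np.abs(beta_std) > 1e-10)
    if support.size:
        signs = np.sign(beta_std[support])
        Xsup = Xs[:, support]
        z = np.concatenate([[b0], beta_std[support]])
        for _ in range(100):
            eta = z[0] + Xsup @ z[1:]
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = prob * (1 - prob)
            grad = np.concatenate(
                [[np.sum(prob - y) / m], Xsup.T @ (prob - y) / m + lam * signs]
            )
            H = np.empty((1 + support.size, 1 + support.size))
            H[0, 0] = w.sum() / m
            H[0, 1:] = H[1:, 0] = w @ Xsup / m
            H[1:, 1:] = Xsup.T @ (w[:, None] * Xsup) / m
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            z = z - step
            if np.abs(step).max() < 1e-14:
                break
        if np.all(np.sign(z[1:]) == signs):
            polished = np.zeros(p)
            polished[support] = z[1:]
            eta = z[0] + Xs @ polished
            fun_p = float(
                np.sum(np.logaddexp(0, eta) - y * eta) / m
                + lam * np.abs(polished).sum()
            )
            if fun_p <= fun:
                beta_std, b0, fun = polished, z[0], fun_p
    return beta_std / sd, fun


def test_lambda_grid_shape_and_ratio(rng):
    table = random_feature_table(rng)
    grid = make_lambda_grid(table)
    assert len(grid) == 100
    assert grid[0] / grid[-1] == pytest.approx(100.0, rel=1e-10)
    assert np.all(np.diff(grid) < 0)
    # log-equispaced
    ratios = grid[1:] / grid[:-1]
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)


def test_all_coefficients_zero_at_lambda_max(rng):
    table = random_feature_table(rng, p=8, m=20)
    grid = make_lambda_grid(table)
    coefs, _ = lasso_logistic_path(table, grid[:1])
    assert np.all(coefs[0] == 0)
    # and strictly below lambda_max some coefficient activates eventually
    coefs_all, _ = lasso_logistic_path(table, grid)
    assert np.any(coefs_all[-1] != 0)


def test_path_matches_direct_minimization_oracle():
    """Tiny instances: coordinate descent agrees with a generic convex
    minimizer (L-BFGS-B on the split-variable objective, Newton-polished on
    its own support) in both objective value and coefficients."""
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        table = random_feature_table(rng, p=3, m=8)
        grid = make_lambda_grid(table, n_lambdas=10)
        coefs, icpts = lasso_logistic_path(table, grid, tol=1e-16)
        for li in (2, 4, 6):
            ref, obj_ref = lbfgs_oracle(table, grid[li])
            obj_mine = penalized_objective(table, grid[li], coefs[li], icpts[li])
            assert obj_mine <= obj_ref + 1e-9
            np.testing.assert_allclose(coefs[li], ref, atol=1e-6)


def test_planted_feature_enters_the_path_first():
    """A 3-SD group effect on one feature makes it the first to activate."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 40))
        y = np.array([1] * 20 + [0] * 20)
        X[4, y == 1] += 3.0
        table = FeatureTable(X, [f"f{i}" for i in range(10)], y)
        coefs, _ = lasso_logistic_path(table, make_lambda_grid(table))
        first = np.argmax(np.any(coefs != 0, axis=1))
        if coefs[first].nonzero()[0].tolist() == [4]:
            hits += 1
    assert hits >= 18


def test_loocv_selects_the_informative_feature():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(5, 30))
    y = np.array([1] * 15 + [0] * 15)
    X[2, y == 1] += 4.0
    table = FeatureTable(X, [f"f{i}" for i in range(5)], y)
    path = select_lambda_loocv(table)
    assert "f2" in path.selected_features
    assert path.lambdas[0] > path.selected_lambda  # interior optimum
    assert path.deviances.min() == path.deviances[path.selected_index]


def test_pure_noise_selects_few_features():
    """With label-independent features and the study's sample size, the
    minimum-deviance model is sparse in the large majority of seeds."""
    lean = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        table = random_feature_table(rng, p=20, m=40)
        path = select_lambda_loocv(table)
        if len(path.selected_features) <= 2:
            lean += 1
    assert lean >= 15


def test_deviance_at_all_zero_lambda_is_the_null_model_deviance(rng):
    """A penalty large enough to zero every fold's coefficients makes the
    LOOCV deviance equal the intercept-only model's (the full-sample
    lambda_max need not dominate every leave-one-out fold's lambda_max, so
    the grid is scaled up to guarantee all-zero fits)."""
    table = random_feature_table(rng, p=6, m=12)
    grid = 3.0 * make_lambda_grid(table)
    path = select_lambda_loocv(table, grid)
    y = table.labels.astype(float)
    null_dev = 0.0
    for i in range(12):
        ybar = np.delete(y, i).mean()
        null_dev += binomial_deviance(y[i : i + 1], np.array([ybar]))
    assert path.deviances[0] == pytest.approx(null_dev, rel=1e-6)


def test_loocv_is_invariant_to_participant_order(rng):
    table = random_feature_table(rng, p=8, m=14)
    perm = np.random.default_rng(1).permutation(14)
    permuted = FeatureTable(
        table.values[:, perm],
        table.feature_names,
        table.labels[perm],
        participant_ids=[table.participant_ids[i] for i in perm],
    )
    a = select_lambda_loocv(table)
    b = select_lambda_loocv(permuted)
    assert a.selected_lambda == pytest.approx(b.selected_lambda)
    assert a.selected_features == b.selected_features
    np.testing.assert_allclose(a.deviances, b.deviances, rtol=1e-8)


def test_selected_features_ordering_and_empty_case(rng):
    table = random_feature_table(rng, p=6, m=16)
    grid = make_lambda_grid(table)
    path = select_lambda_loocv(table, grid)
    coefs = path.coefficients
    mags = np.abs(coefs[np.flatnonzero(coefs)])
    names = selected_features(path)
    assert len(names) == len(mags)
    got = [abs(coefs[path.feature_names.index(n)]) for n in names]
    assert got == sorted(got, reverse=True)
    # all-zero solution -> empty list
    import dataclasses
    empty = dataclasses.replace(path, coefficients=np.zeros_like(coefs))
    assert selected_features(empty) == []


def test_invalid_grid_rejected(rng):
    table = random_feature_table(rng)
    with pytest.raises(ValueError, match="descending"):
        lasso_logistic_path(table, np.array([0.1, 0.2]))
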