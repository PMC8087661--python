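"""L1-penalized logistic regression along a regularization path.

Feature selection minimizes the penalized binomial objective

    (1/N) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i] + lambda * ||beta||_1,
    eta_i = beta_0 + x_i . beta

over a descending grid of 100 lambda values, log-equispaced from lambda_max
(the smallest penalty at which every coefficient is zero) down to
0.01 * lambda_max. The best lambda minimizes the leave-one-out
cross-validated binomial deviance; features with nonzero coefficients at
that lambda are the selected features.

The solver is the standard iteratively-reweighted least squares scheme with
cyclic coordinate descent on the weighted quadratic approximation,
warm-started along the path, with features standardized internally
(coefficients are reported on the original scale). The intercept is never
penalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .tables import FeatureTable

N_LAMBDAS = 100
LAMBDA_RATIO = 0.01
PROB_CLIP = 1e-8
_TOL = 1e-12
_MAX_OUTER = 200
_MAX_INNER = 2000


@dataclass
class LassoPath:
    """Fitted path plus the LOOCV-deviance selection result."""

    lambdas: np.ndarray
    deviances: np.ndarray
    selected_lambda: float
    coefficients: np.ndarray  # original-scale coefficients at selected lambda
    intercept: float
    feature_names: list[str]
    family: str = ""
    coef_path: np.ndarray | None = None  # (n_lambdas, p), original scale

    @property
    def selected_index(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.selected_lambda)))

    @property
    def selected_features(self) -> list[str]:
        return selected_features(self)


@njit(cache=False)
def _fit_path(X, y, lambdas, tol, max_outer, max_inner):  # pragma: no cover
    """Warm-started coordinate-descent path on standardized features."""
    m, p = X.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    xsq = np.empty(p)

    for li in range(n_lam):
        lam = lambdas[li]
        prev_obj = 1e300
        for _ in range(max_outer):
            # quadratic approximation at the current linear predictor
            eta = np.full(m, b0)
            for j in range(p):
                if beta[j] != 0.0:
                    eta += beta[j] * X[:, j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            for i in range(m):
                if prob[i] < 1e-9:
                    prob[i] = 1e-9
                elif prob[i] > 1.0 - 1e-9:
                    prob[i] = 1.0 - 1e-9
            w = prob * (1.0 - prob)
            z = eta + (y - prob) / w
            r = z - eta  # working residual
            wsum = w.sum()
            for j in range(p):
                xsq[j] = (w * X[:, j] * X[:, j]).sum() / m

            for _ in range(max_inner):
                max_step = 0.0
                d0 = (w * r).sum() / wsum
                if d0 != 0.0:
                    b0 += d0
                    r -= d0
                    step = wsum / m * d0 * d0
                    if step > max_step:
                        max_step = step
                for j in range(p):
                    grad = (w * X[:, j] * r).sum() / m + xsq[j] * beta[j]
                    if grad > lam:
                        bnew = (grad - lam) / xsq[j]
                    elif grad < -lam:
                        bnew = (grad + lam) / xsq[j]
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        r -= d * X[:, j]
                        step = xsq[j] * d * d
                        if step > max_step:
                            max_step = step
                if max_step < tol:
                    break

            # true penalized objective for the outer stopping rule
            eta = np.full(m, b0)
            for j in range(p):
                if beta[j] != 0.0:
                    eta += beta[j] * X[:, j]
            obj = 0.0
            for i in range(m):
                if eta[i] > 0:
                    obj += eta[i] + np.log1p(np.exp(-eta[i])) - y[i] * eta[i]
                else:
                    obj += np.log1p(np.exp(eta[i])) - y[i] * eta[i]
            obj /= m
            obj += lam * np.abs(beta).sum()
            if prev_obj - obj < tol * (1.0 + np.abs(obj)):
                break
            prev_obj = obj

        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale a participants x features design; population SD."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return np.asfortranarray((values - mu) / sd), mu, sd


def make_lambda_grid(
    table: FeatureTable, n_lambdas: int = N_LAMBDAS, ratio: float = LAMBDA_RATIO
) -> np.ndarray:
    """Descending log-equispaced grid from lambda_max to ratio * lambda_max.

    lambda_max is the smallest penalty at which the fit is all-zero: with
    standardized features and the null-model probabilities ybar, the KKT
    conditions give lambda_max = max_j |x_j . (y - ybar)| / N.
    """
    y = table.labels.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant")
    Xs, _, _ = _standardize(table.design())
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))
    # nudge off the KKT boundary so the first fit is exactly all-zero
    lam_max *= 1.0 + 1e-10
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


def lasso_logistic_path(
    table: FeatureTable, lambdas: np.ndarray, tol: float = _TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (original scale) and intercepts along the lambda grid.

    Returns ``(coefs, intercepts)`` with ``coefs`` of shape (n_lambdas, p).
    ``tol`` is the coordinate-descent/IRLS convergence threshold; the
    default balances speed against accuracy well beyond feature-selection
    needs, and can be tightened towards machine precision.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or len(lambdas) == 0 or np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be a nonempty strictly-descending grid")
    X = table.design()
    y = table.labels.astype(float)
    Xs, mu, sd = _standardize(X)
    coefs_std, icpt_std = _fit_path(Xs, y, lambdas, tol, _MAX_OUTER, _MAX_INNER)
    if not np.all(np.isfinite(coefs_std)):
        bad = int(np.where(~np.isfinite(coefs_std).all(axis=1))[0][0])
        raise RuntimeError(f"path fit did not converge at lambda index {bad}")
    coefs = coefs_std / sd
    intercepts = icpt_std - coefs_std @ (mu / sd)
    return coefs, intercepts


def binomial_deviance(y: np.ndarray, p_hat: np.ndarray) -> float:
    """-2 log-likelihood of binary outcomes, probabilities clipped."""
    p_hat = np.clip(p_hat, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-2.0 * np.sum(y * np.log(p_hat) + (1 - y) * np.log(1 - p_hat)))


def select_lambda_loocv(
    table: FeatureTable, lambdas: np.ndarray | None = None, tol: float = _TOL
) -> LassoPath:
    """Choose lambda by minimum leave-one-out binomial deviance.

    For every lambda the model is refit on each N-1 subset (features
    re-standardized within the training fold) and the held-out deviance
    summed across folds. Ties in deviance break toward the larger lambda
    (the sparser model). Coefficients reported at the selected lambda come
    from a full-sample fit.
    """
    m = table.n_participants
    if m < 3:
        raise ValueError("LOOCV needs at least 3 participants")
    if lambdas is None:
        lambdas = make_lambda_grid(table)
    lambdas = np.asarray(lambdas, dtype=float)
    X = table.design()
    y = table.labels.astype(float)
    deviance_terms = np.zeros((len(lambdas), m))
    for i in range(m):
        keep = np.ones(m, dtype=bool)
        keep[i] = False
        Xs, mu, sd = _standardize(X[keep])
        coefs_std, icpt_std = _fit_path(
            Xs, y[keep], lambdas, tol, _MAX_OUTER, _MAX_INNER
        )
        coefs = coefs_std / sd
        intercepts = icpt_std - coefs_std @ (mu / sd)
        # held-out probability per lambda
        eta = intercepts + coefs @ X[i]
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        p_hat = np.clip(p_hat, PROB_CLIP, 1.0 - PROB_CLIP)
        deviance_terms[:, i] = -2.0 * (
            y[i] * np.log(p_hat) + (1 - y[i]) * np.log(1 - p_hat)
        )
    deviances = deviance_terms.sum(axis=1)
    best = int(np.argmin(deviances))  # grid descends, argmin takes first == larger lambda
    coefs_full, icpt_full = lasso_logistic_path(table, lambdas, tol)
    return LassoPath(
        lambdas=lambdas,
        deviances=deviances,
        selected_lambda=float(lambdas[best]),
        coefficients=coefs_full[best],
        intercept=float(icpt_full[best]),
        feature_names=list(table.feature_names),
        family=table.family,
        coef_path=coefs_full,
    )


def selected_features(path: LassoPath) -> list[str]:
    """Nonzero-coefficient feature names, descending |coefficient|."""
    coef = path.coefficients
    nz = np.flatnonzero(coef)
    order = nz[np.argsort(-np.abs(coef[nz]), kind="stable")]
    return [path.feature_names[j] for j in order]
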