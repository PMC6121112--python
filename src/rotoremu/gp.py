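"""Gaussian-process regression with a linear mean and Matern-5/2 ARD kernel.

The covariance between two parameter points theta, theta' is

    k(theta, theta') = sigma^2 (1 + sqrt(5) r + 5 r^2 / 3) exp(-sqrt(5) r)
                       + sigma_n^2 delta_{theta, theta'},
    r^2 = sum_i (theta_i - theta'_i)^2 / l_i^2,

with one lengthscale per dimension, so maximum-likelihood fitting performs
automatic relevance determination: dimensions that do not influence the
target are assigned large lengthscales.  The mean is an explicit linear
trend ``beta_0 + sum_i beta_i theta_i`` whose coefficients are profiled out
of the marginal likelihood by generalized least squares at every
hyperparameter evaluation.  Inputs are expected on the unit hypercube;
targets are standardized internally and restored on prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["GPModel", "matern52_ard", "gp_train", "gp_predict"]

JITTER_FLOOR = 1e-8  # on the standardized-target scale

#: hyperparameter search box (normalized inputs / standardized targets)
L_BOUNDS = (0.05, 5.0)
SIGMA_BOUNDS = (0.1, 3.0)
SIGMA_N_BOUNDS = (1e-4, 0.5)


def matern52_ard(theta, theta_prime, lengthscales, sigma: float,
                 sigma_n: float = 0.0) -> float:
    """Matern-5/2 ARD covariance between two points.

    The noise term contributes only when the two points are exactly equal
    (Kronecker delta).
    """
    t1 = np.asarray(theta, float).ravel()
    t2 = np.asarray(theta_prime, float).ravel()
    ls = np.broadcast_to(np.asarray(lengthscales, float).ravel(), t1.shape)
    r = np.sqrt(np.sum(((t1 - t2) / ls) ** 2))
    val = sigma ** 2 * (1.0 + np.sqrt(5) * r + 5.0 * r ** 2 / 3.0) * \
        np.exp(-np.sqrt(5) * r)
    if np.array_equal(t1, t2):
        val += sigma_n ** 2
    return float(val)


def _sq_dists(X1, X2, ls):
    A = X1 / ls
    B = X2 / ls
    d2 = np.sum(A ** 2, 1)[:, None] + np.sum(B ** 2, 1)[None, :] \
        - 2.0 * A @ B.T
    return np.maximum(d2, 0.0)


def _kernel(X1, X2, ls, sigma):
    r = np.sqrt(_sq_dists(X1, X2, ls))
    s5r = np.sqrt(5) * r
    return sigma ** 2 * (1.0 + s5r + s5r ** 2 / 3.0) * np.exp(-s5r)


@dataclass
class GPModel:
    """Trained GP: hyperparameters plus cached training factorization."""

    X: np.ndarray                 # (n, D), unit-hypercube inputs
    y: np.ndarray                 # (n,), raw targets
    lengthscales: np.ndarray      # (D,)
    sigma: float
    sigma_n: float
    beta: np.ndarray              # (D + 1,), linear mean on standardized y
    y_mean: float
    y_std: float
    log_marginal_likelihood: float
    _chol: np.ndarray = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    def predict(self, X_star, chunk: int = 20000):
        return gp_predict(self, X_star, chunk=chunk)

    @property
    def beta_raw(self) -> np.ndarray:
        """Linear-mean coefficients on the raw target scale."""
        b = self.beta * self.y_std
        b0 = b[0] + self.y_mean
        return np.concatenate([[b0], b[1:]])


def _design(X):
    return np.hstack([np.ones((len(X), 1)), X])


def _chol_with_jitter(K):
    n = len(K)
    jitter = 0.0
    while True:
        try:
            return linalg.cholesky(K + jitter * np.eye(n) if jitter else K,
                                   lower=True)
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
            if jitter > 1e-2:
                raise linalg.LinAlgError(
                    "training covariance is singular even after jitter "
                    "escalation")


def _fit_beta_and_lml(X, z, ls, sigma, sigma_n):
    """Profiled-beta log marginal likelihood; returns (lml, beta, L, alpha)."""
    n = len(z)
    K = _kernel(X, X, ls, sigma)
    K[np.diag_indices_from(K)] += max(sigma_n, JITTER_FLOOR) ** 2
    L = _chol_with_jitter(K)
    H = _design(X)
    Kinv_H = linalg.cho_solve((L, True), H)
    Kinv_z = linalg.cho_solve((L, True), z)
    A = H.T @ Kinv_H
    beta = linalg.solve(A, H.T @ Kinv_z, assume_a="pos")
    resid = z - H @ beta
    alpha = linalg.cho_solve((L, True), resid)
    lml = -0.5 * resid @ alpha - np.sum(np.log(np.diag(L))) \
        - 0.5 * n * np.log(2 * np.pi)
    return float(lml), beta, L, alpha


def _nll_and_grad(X, z, log_theta, opt_noise, fix_sigma_n):
    """Negative profiled log likelihood and its gradient in log parameters.

    Because beta-hat solves the GLS normal equations, H^T alpha = 0 and the
    beta-dependence drops out of the gradient (envelope theorem):
    d(-lml)/dphi = -1/2 alpha^T dK alpha + 1/2 tr(K^-1 dK).
    """
    n, D = X.shape
    ls = np.exp(log_theta[:D])
    sigma = np.exp(log_theta[D])
    sigma_n = np.exp(log_theta[D + 1]) if opt_noise else fix_sigma_n

    r2 = _sq_dists(X, X, ls)
    r = np.sqrt(r2)
    s5r = np.sqrt(5) * r
    E = np.exp(-s5r)
    Kf = (1.0 + s5r + s5r ** 2 / 3.0) * E
    K = sigma ** 2 * Kf
    K[np.diag_indices_from(K)] += max(sigma_n, JITTER_FLOOR) ** 2
    L = _chol_with_jitter(K)
    H = _design(X)
    Kinv_H = linalg.cho_solve((L, True), H)
    Kinv_z = linalg.cho_solve((L, True), z)
    A = H.T @ Kinv_H
    beta = linalg.solve(A, H.T @ Kinv_z, assume_a="pos")
    resid = z - H @ beta
    alpha = linalg.cho_solve((L, True), resid)
    nll = 0.5 * resid @ alpha + np.sum(np.log(np.diag(L))) \
        + 0.5 * n * np.log(2 * np.pi)

    Kinv = linalg.cho_solve((L, True), np.eye(n))
    grad = np.empty(len(log_theta))
    # d/d log l_i: sigma^2 (5/3)(1 + sqrt5 r) E * d_i^2 / l_i^2
    C = sigma ** 2 * (5.0 / 3.0) * (1.0 + s5r) * E
    M = Kinv - np.outer(alpha, alpha)  # tr(Kinv dK) - a^T dK a = sum(M * dK)
    for i in range(D):
        d2 = (X[:, i][:, None] - X[:, i][None, :]) ** 2 / ls[i] ** 2
        grad[i] = 0.5 * np.sum(M * (C * d2))
    dK_sigma = 2.0 * sigma ** 2 * Kf
    grad[D] = 0.5 * np.sum(M * dK_sigma)
    if opt_noise:
        grad[D + 1] = 0.5 * np.trace(M) * 2.0 * sigma_n ** 2
    return nll, grad


def gp_train(X, y, restarts: int = 10, seed: int = 0,
             fix_sigma_n: float | None = None) -> GPModel:
    """Maximum-marginal-likelihood fit of the GP hyperparameters.

    Multi-start L-BFGS-B over log lengthscales, log sigma and (unless
    ``fix_sigma_n`` is given) log sigma_n, with starts drawn log-uniformly
    from the search box.  Targets are standardized internally.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, D) matching y")
    if not np.all(np.isfinite(y)):
        raise ValueError("gp_train does not accept missing targets")
    n, D = X.shape
    y_mean, y_std = float(y.mean()), float(y.std())
    if y_std < 1e-12:
        # constant target: the linear mean absorbs everything
        ls = np.ones(D)
        lml, beta, L, alpha = _fit_beta_and_lml(X, np.zeros(n), ls,
                                                SIGMA_BOUNDS[0], JITTER_FLOOR)
        return GPModel(X=X, y=y, lengthscales=ls, sigma=SIGMA_BOUNDS[0],
                       sigma_n=JITTER_FLOOR, beta=beta, y_mean=y_mean,
                       y_std=1.0, log_marginal_likelihood=lml, _chol=L,
                       _alpha=alpha)
    z = (y - y_mean) / y_std

    opt_noise = fix_sigma_n is None

    def negloglik(log_theta):
        try:
            return _nll_and_grad(X, z, log_theta, opt_noise, fix_sigma_n)
        except linalg.LinAlgError:
            return 1e10, np.zeros_like(log_theta)

    rng = np.random.default_rng(seed)
    lb = np.log([L_BOUNDS[0]] * D + [SIGMA_BOUNDS[0]]
                + ([SIGMA_N_BOUNDS[0]] if opt_noise else []))
    ub = np.log([L_BOUNDS[1]] * D + [SIGMA_BOUNDS[1]]
                + ([SIGMA_N_BOUNDS[1]] if opt_noise else []))
    starts = [np.log(np.concatenate([np.ones(D), [1.0],
                                     [0.05] if opt_noise else []]))]
    for _ in range(max(0, restarts - 1)):
        starts.append(rng.uniform(lb, ub))

    best = None
    for x0 in starts:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", jac=True,
                                bounds=list(zip(lb, ub)))
        if best is None or res.fun < best.fun:
            best = res
    ls = np.exp(best.x[:D])
    sigma = float(np.exp(best.x[D]))
    sigma_n = float(np.exp(best.x[D + 1])) if opt_noise else float(fix_sigma_n)
    lml, beta, L, alpha = _fit_beta_and_lml(X, z, ls, sigma, sigma_n)
    return GPModel(X=X, y=y, lengthscales=ls, sigma=sigma, sigma_n=sigma_n,
                   beta=beta, y_mean=y_mean, y_std=y_std,
                   log_marginal_likelihood=lml, _chol=L, _alpha=alpha)


def gp_predict(model: GPModel, X_star, chunk: int = 20000):
    """Posterior mean and variance (raw target scale) at ``X_star``.

    The predictive variance excludes the noise term, so it vanishes at
    training points when sigma_n sits at the jitter floor and reverts to
    sigma^2 far from all data.  Large batches are processed in chunks.
    """
    X_star = np.atleast_2d(np.asarray(X_star, float))
    means = np.empty(len(X_star))
    variances = np.empty(len(X_star))
    for a in range(0, len(X_star), chunk):
        Xs = X_star[a:a + chunk]
        Ks = _kernel(Xs, model.X, model.lengthscales, model.sigma)
        Hs = _design(Xs)
        mean = Hs @ model.beta + Ks @ model._alpha
        V = linalg.solve_triangular(model._chol, Ks.T, lower=True)
        var = model.sigma ** 2 - np.sum(V ** 2, axis=0)
        means[a:a + chunk] = mean * model.y_std + model.y_mean
        variances[a:a + chunk] = np.maximum(var, 0.0) * model.y_std ** 2
    return means, variances
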