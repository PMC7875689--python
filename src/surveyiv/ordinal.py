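"""Proportional-odds (cumulative-logit) maximum likelihood, tuned for speed.

The conditional-independence tests refit a cumulative-logit model thousands of
times inside Monte-Carlo experiments, so the fit is written directly against
the analytic log-likelihood and gradient (L-BFGS-B with warm starts) instead
of a generic MLE wrapper. Thresholds are parametrized as (t1, log-spacings) to
keep them ordered.

Model: P(Y <= k | x) = logit^{-1}(theta_k - x'beta), k = 1..J-1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["PolrFit", "fit_proportional_odds", "likelihood_ratio_test", "score_test"]


@dataclass(frozen=True)
class PolrFit:
    """Fitted cumulative-logit model."""

    thresholds: np.ndarray
    beta: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_categories: int
    raw_params: np.ndarray

    def predict_cdf(self, X: np.ndarray) -> np.ndarray:
        """P(Y <= k | x) for k = 1..J-1, shape (n, J-1)."""
        eta = X @ self.beta
        return expit(self.thresholds[np.newaxis, :] - eta[:, np.newaxis])


def _unpack(par: np.ndarray, J: int):
    th = np.concatenate([[par[0]], par[0] + np.cumsum(np.exp(par[1:J - 1]))])
    return th, par[J - 1:]


def _negll_grad(par: np.ndarray, y: np.ndarray, X: np.ndarray, J: int):
    """Negative log-likelihood and analytic gradient."""
    th, beta = _unpack(par, J)
    eta = X @ beta
    upper = y < J - 1
    lower = y > 0
    thU = np.where(upper, th[np.minimum(y, J - 2)], 0.0)
    thL = np.where(lower, th[np.maximum(y - 1, 0)], 0.0)
    FU = np.where(upper, expit(thU - eta), 1.0)
    FL = np.where(lower, expit(thL - eta), 0.0)
    P = np.clip(FU - FL, 1e-300, None)
    nll = -float(np.log(P).sum())
    fU = np.where(upper, FU * (1.0 - FU), 0.0)
    fL = np.where(lower, FL * (1.0 - FL), 0.0)
    inv = 1.0 / P
    gbeta = X.T @ ((fU - fL) * inv)
    gth = np.zeros(J - 1)
    np.add.at(gth, np.minimum(y, J - 2), np.where(upper, -fU * inv, 0.0))
    np.add.at(gth, np.maximum(y - 1, 0), np.where(lower, fL * inv, 0.0))
    gpar = np.empty_like(par)
    # chain rule through theta_k = par0 + sum_{i<k} exp(par_i)
    rev = np.cumsum(gth[::-1])[::-1]
    gpar[0] = rev[0]
    if J > 2:
        gpar[1:J - 1] = rev[1:] * np.exp(par[1:J - 1])
    gpar[J - 1:] = gbeta
    return nll, gpar


def _start_values(y: np.ndarray, J: int, p: int) -> np.ndarray:
    counts = np.bincount(y, minlength=J).astype(float)
    cum = np.clip(np.cumsum(counts)[:-1] / counts.sum(), 1e-4, 1 - 1e-4)
    th0 = np.log(cum / (1.0 - cum))
    spacings = np.clip(np.diff(th0), 1e-4, None)
    return np.concatenate([[th0[0]], np.log(spacings), np.zeros(p)])


def fit_proportional_odds(y: np.ndarray, X: np.ndarray,
                          start: np.ndarray | None = None) -> PolrFit:
    """Fit the cumulative-logit model by maximum likelihood.

    ``y`` must use contiguous codes 0..J-1 (every category observed);
    ``X`` is the predictor matrix without an intercept (absorbed by the
    thresholds). ``start`` warm-starts the optimizer, e.g. from a nested fit.
    """
    y = np.asarray(y, dtype=np.intp)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, np.newaxis]
    J = int(y.max()) + 1
    if J < 2:
        raise ValueError("outcome collapses to a single category")
    observed = np.bincount(y, minlength=J)
    if (observed == 0).any():
        raise ValueError("outcome codes must be contiguous 0..J-1 with every category observed")
    n, p = X.shape
    x0 = _start_values(y, J, p) if start is None else np.asarray(start, dtype=float)
    res = minimize(_negll_grad, x0, args=(y, X, J), jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8})
    th, beta = _unpack(res.x, J)
    return PolrFit(th, beta, -float(res.fun), bool(res.success), n, J, res.x)


def compress_codes(y: np.ndarray) -> np.ndarray:
    """Relabel an integer outcome to contiguous 0..J-1 over observed values."""
    _, inv = np.unique(np.asarray(y), return_inverse=True)
    return inv.astype(np.intp)


def likelihood_ratio_test(y: np.ndarray, X0: np.ndarray, x_add: np.ndarray):
    """1-df likelihood-ratio test for adding one column to the model.

    Fits Y ~ X0 and Y ~ [X0, x_add]; returns (statistic, p, fallback_used).
    The full model warm-starts from the nested fit. If either fit fails to
    converge, falls back to the efficient score test on the same nesting.
    """
    y = compress_codes(y)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if X0.shape[0] != len(y):
        X0 = X0.T
    x_add = np.asarray(x_add, dtype=float).reshape(-1)
    if np.ptp(x_add) == 0:  # constant column adds no information
        return 0.0, 1.0, False
    fit0 = fit_proportional_odds(y, X0)
    J = fit0.n_categories
    warm = np.concatenate([fit0.raw_params, [0.0]])
    X1 = np.column_stack([X0, x_add])
    fit1 = fit_proportional_odds(y, X1, start=warm)
    if fit0.converged and fit1.converged and fit1.loglik >= fit0.loglik - 1e-6:
        stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
        return stat, float(stats.chi2.sf(stat, 1)), False
    stat, p = score_test(y, X0, x_add, fit0)
    return stat, p, True


def score_test(y: np.ndarray, X0: np.ndarray, x_add: np.ndarray,
               fit0: PolrFit | None = None):
    """Efficient score (Rao) test for one added column, 1 df.

    Evaluates the full-model score at the restricted MLE and inverts the
    observed information (finite differences of the analytic gradient).
    """
    y = compress_codes(y)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if X0.shape[0] != len(y):
        X0 = X0.T
    if fit0 is None:
        fit0 = fit_proportional_odds(y, X0)
    J = fit0.n_categories
    X1 = np.column_stack([X0, np.asarray(x_add, dtype=float).reshape(-1)])
    par = np.concatenate([fit0.raw_params, [0.0]])
    _, g = _negll_grad(par, y, X1, J)
    g = -g  # gradient of the log-likelihood
    k = par.size
    info = np.empty((k, k))
    h = 1e-5
    for j in range(k):
        step = np.zeros(k)
        step[j] = h
        _, gp = _negll_grad(par + step, y, X1, J)
        _, gm = _negll_grad(par - step, y, X1, J)
        info[:, j] = (gp - gm) / (2.0 * h)  # d(neg grad)/d par_j = observed info
    info = 0.5 * (info + info.T)
    try:
        stat = float(g @ np.linalg.solve(info, g))
    except np.linalg.LinAlgError:
        stat = float(g @ np.linalg.pinv(info) @ g)
    stat = max(0.0, stat)
    return stat, float(stats.chi2.sf(stat, 1))
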