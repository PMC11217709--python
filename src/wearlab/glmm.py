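"""Maximum-likelihood random-intercept logistic regression.

Fits the two-level model

    y_ij ~ Bernoulli(p_ij),   logit(p_ij) = x_ij' beta + b_i,
    b_i ~ Normal(0, sigma^2),

by maximizing the marginal likelihood, integrating each cluster's random
intercept with adaptive Gauss-Hermite quadrature: the integrand is recentred
at its mode (found by a per-cluster Newton iteration) and rescaled by the
local curvature before the Hermite nodes are applied.  With a single
quadrature node the method reduces to the Laplace approximation, which is
used as a fallback when the mode search fails.

Standard errors are Wald, from the numerically differentiated Hessian of the
marginal log-likelihood at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class GlmmResult:
    """Fitted random-intercept logistic model."""

    converged: bool
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    se: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma: float = np.nan
    loglik: float = np.nan
    n_obs: int = 0
    n_groups: int = 0
    n_quad: int = 0
    method: str = "agq"
    message: str = ""
    separation: bool = False

    def wald(self, j: int, level: float = 0.95):
        """(estimate, ci_low, ci_high, p) for coefficient ``j``, log-odds scale."""
        z = stats.norm.ppf(0.5 + level / 2)
        b, s = self.beta[j], self.se[j]
        p = 2 * stats.norm.sf(abs(b / s)) if s > 0 else np.nan
        return b, b - z * s, b + z * s, p


def _cluster_modes(eta0, y, group, n_groups, sigma2, b0=None, tol=1e-9, max_iter=50):
    """Newton search for the per-cluster mode of the integrand.

    Returns (b_hat, h) where h = (-g'')^{-1/2} at the mode.
    """
    b = np.zeros(n_groups) if b0 is None else b0.copy()
    for _ in range(max_iter):
        eta = eta0 + b[group]
        mu = special.expit(eta)
        grad = np.bincount(group, weights=y - mu, minlength=n_groups) - b / sigma2
        info = np.bincount(group, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / sigma2
        step = grad / info
        # dampen large steps for stability
        step = np.clip(step, -5.0, 5.0)
        b += step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + b[group]
    mu = special.expit(eta)
    info = np.bincount(group, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / sigma2
    return b, 1.0 / np.sqrt(info)


def _marginal_loglik(theta, X, y, group, starts, n_groups, nodes, logw):
    beta = theta[:-1]
    log_sigma = theta[-1]
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma

    eta0 = X @ beta
    b_hat, h = _cluster_modes(eta0, y, group, n_groups, sigma2)

    # quadrature points per cluster: b = b_hat + sqrt(2) h a_k
    B = b_hat[:, None] + np.sqrt(2.0) * h[:, None] * nodes[None, :]
    eta = eta0[:, None] + B[group]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    g = np.add.reduceat(ll_obs, starts, axis=0)
    g += -0.5 * B * B / sigma2 - log_sigma - _LOG_SQRT_2PI

    # log L_i = log(sqrt(2) h_i) + logsumexp_k(log w_k + a_k^2 + g_ik)
    contrib = logw[None, :] + nodes[None, :] ** 2 + g
    m = contrib.max(axis=1)
    log_li = 0.5 * np.log(2.0) + np.log(h) + m + np.log(
        np.exp(contrib - m[:, None]).sum(axis=1)
    )
    return float(log_li.sum())


def fit_random_intercept_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 10,
    max_abs_beta: float = 15.0,
) -> GlmmResult:
    """Fit the model; ``X`` must include an intercept column.

    ``groups`` are arbitrary cluster labels.  ``n_quad`` adaptive
    Gauss-Hermite nodes are used (1 = Laplace).  A fitted coefficient with
    magnitude above ``max_abs_beta`` is reported as probable complete
    separation with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _, group = np.unique(np.asarray(groups), return_inverse=True)
    order = np.argsort(group, kind="stable")
    X, y, group = X[order], y[order], group[order]
    n_groups = int(group.max()) + 1
    starts = np.searchsorted(group, np.arange(n_groups))

    if X.ndim != 2 or len(X) != len(y) or len(y) != len(group):
        raise ValueError("X, y, groups must have matching first dimensions")

    nodes, weights = special.roots_hermite(n_quad)
    logw = np.log(weights)

    # start at the pooled logistic solution, sigma = 1
    beta0 = _pooled_logit(X, y)
    theta0 = np.concatenate([beta0, [0.0]])

    def nll(theta):
        return -_marginal_loglik(theta, X, y, group, starts, n_groups, nodes, logw)

    bounds = [(-50.0, 50.0)] * X.shape[1] + [(np.log(1e-4), np.log(50.0))]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    method = "agq" if n_quad > 1 else "laplace"
    if not res.success:
        # Laplace fallback
        n1, w1 = special.roots_hermite(1)
        logw1 = np.log(w1)

        def nll_laplace(t):
            return -_marginal_loglik(t, X, y, group, starts, n_groups, n1, logw1)

        res2 = optimize.minimize(
            nll_laplace, theta0, method="L-BFGS-B", bounds=bounds
        )
        if res2.success:
            res, method = res2, "laplace"
            nll = nll_laplace

    theta = res.x
    beta = theta[:-1]
    sigma = float(np.exp(theta[-1]))
    separation = bool(np.any(np.abs(beta) > max_abs_beta))

    se = np.full(X.shape[1], np.nan)
    ok = res.success and not separation
    if ok:
        try:
            hess = numdiff.approx_hess(theta, nll)
            cov = np.linalg.inv(hess)
            var = np.diag(cov)[: X.shape[1]]
            if np.any(var <= 0) or not np.all(np.isfinite(var)):
                ok = False
            else:
                se = np.sqrt(var)
        except np.linalg.LinAlgError:
            ok = False

    return GlmmResult(
        converged=ok,
        beta=beta,
        se=se,
        sigma=sigma,
        loglik=-float(res.fun),
        n_obs=len(y),
        n_groups=n_groups,
        n_quad=n_quad,
        method=method,
        message=str(res.message),
        separation=separation,
    )


def _pooled_logit(X, y, max_iter=25):
    """Ridge-stabilized Newton solve of the pooled logistic model."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (X * w[:, None]).T @ X + 1e-6 * np.eye(X.shape[1])
        g = X.T @ (y - mu) - 1e-6 * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return np.clip(beta, -10, 10)
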