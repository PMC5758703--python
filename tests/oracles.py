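"""Independent oracles for the test suite.

Everything here is deliberately written against the *math*, not against the
package's code paths: direct arithmetic, dense-grid quadrature and
closed-form conjugate algebra, so disagreement points at the implementation.
"""

from __future__ import annotations

import math

import numpy as np


def waic_by_hand(loglik):
    """Deviance-scale WAIC by direct arithmetic (python floats, no shortcuts)."""
    ll = [list(map(float, row)) for row in loglik]
    S = len(ll)
    n = len(ll[0])
    lppd = 0.0
    p_waic = 0.0
    for i in range(n):
        col = [ll[s][i] for s in range(S)]
        lppd += math.log(sum(math.exp(v) for v in col) / S)
        mean = sum(col) / S
        p_waic += sum((v - mean) ** 2 for v in col) / (S - 1)
    return lppd, p_waic, -2.0 * (lppd - p_waic)


def grid_posterior_single_coefficient(
    y, n, x, alpha, gamma, tau, prior_var, beta_grid, gh_points=80
):
    """Dense-grid posterior of a single coefficient in the binomial hierarchy.

    Model: y ~ Binomial(n, expit(eta)), eta ~ Normal(alpha + gamma*x*beta,
    1/tau), beta ~ Normal(0, prior_var).  The eta integral is evaluated by
    Gauss-Hermite quadrature at every grid point; the return value is the
    normalized posterior density on the grid (trapezoid normalization).
    """
    from numpy.polynomial.hermite_e import hermegauss

    nodes, weights = hermegauss(gh_points)  # probabilists': weight e^{-t^2/2}
    weights = weights / math.sqrt(2.0 * math.pi)
    log_binom_const = (
        math.lgamma(n + 1) - math.lgamma(y + 1) - math.lgamma(n - y + 1)
    )
    sd_eta = 1.0 / math.sqrt(tau)
    log_post = np.empty(len(beta_grid))
    for g, beta in enumerate(beta_grid):
        m = alpha + gamma * x * beta
        eta = m + sd_eta * nodes
        loglik = log_binom_const + y * eta - n * np.logaddexp(0.0, eta)
        lik = float(np.sum(weights * np.exp(loglik)))
        log_post[g] = -0.5 * beta**2 / prior_var + math.log(max(lik, 1e-300))
    log_post -= log_post.max()
    dens = np.exp(log_post)
    dens /= np.trapezoid(dens, beta_grid)
    return dens


def binned_probabilities(grid, density, edges):
    """Integrate a gridded density over bins (open-ended outer bins)."""
    probs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (grid >= lo) & (grid <= hi)
        if mask.sum() < 2:
            probs.append(0.0)
        else:
            probs.append(float(np.trapezoid(density[mask], grid[mask])))
    probs = np.asarray(probs)
    return probs / probs.sum()


def conjugate_weighted_regression(y, X, weights, prior_var):
    """Exact posterior (mean, cov) of beta in y ~ N(X beta, 1/weights) with
    a N(0, prior_var * I) prior — assembled via plain matrix inversion."""
    X = np.asarray(X, dtype=float)
    W = np.diag(np.asarray(weights, dtype=float))
    prior_prec = np.eye(X.shape[1]) / prior_var
    post_cov = np.linalg.inv(prior_prec + X.T @ W @ X)
    post_mean = post_cov @ (X.T @ W @ np.asarray(y, dtype=float))
    return post_mean, post_cov


def normal_normal_update(prior_mean, prior_var, obs, obs_vars):
    """Scalar conjugate normal update, one likelihood term at a time."""
    prec = 1.0 / prior_var
    num = prior_mean / prior_var
    for o, v in zip(obs, obs_vars):
        prec += 1.0 / v
        num += o / v
    return num / prec, 1.0 / prec


def batch_means_se(x, n_batches=30):
    """Standard error of the mean of a correlated sequence via batch means."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    if m < 2:
        raise ValueError("sequence too short for batch means")
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))
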