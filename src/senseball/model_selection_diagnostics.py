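"""WAIC model comparison, convergence diagnostics, posterior predictive checks.

The full-versus-reduced comparison asks whether the sensorimotor covariates
add predictive power beyond age and position.  WAIC is used on the deviance
scale, waic = -2 * (lppd - p_waic), with the variance form of the effective
number of parameters; lower is better, and the pointwise unit is the
(player, league) stint — the likelihood's atomic term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .latent_ability_model import ChainSet, pointwise_loglik

__all__ = [
    "WAICResult",
    "ComparisonVerdict",
    "DiagnosticsReport",
    "compute_waic",
    "compare_models",
    "gelman_rubin",
    "effective_sample_size",
    "posterior_predictive_check",
    "PPCResult",
]


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise: pd.DataFrame  # lppd_i, p_waic_i, waic_i per observation
    n_observations: int

    def __post_init__(self) -> None:
        assert self.p_waic >= 0
        assert np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic))


def compute_waic(loglik: np.ndarray) -> WAICResult:
    """WAIC from a draws x observations pointwise log-likelihood matrix.

    lppd_i = log mean_s exp(loglik[s, i]) (stable log-sum-exp);
    p_waic_i = sample variance over draws; waic = -2 * (lppd - p_waic).
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be a draws x observations matrix")
    S, n = ll.shape
    if S < 2:
        raise ValueError("need at least 2 draws to estimate p_waic")
    if n < 1:
        raise ValueError("need at least 1 observation")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood entries")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    # center on the first draw so constant columns give a variance of exactly 0
    p_i = (ll - ll[0]).var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    pointwise = pd.DataFrame({"lppd": lppd_i, "p_waic": p_i, "waic": waic_i})
    return WAICResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(waic_i.sum()),
        pointwise=pointwise,
        n_observations=n,
    )


@dataclass
class ComparisonVerdict:
    delta_waic: float       # full - reduced; negative favors the full model
    full_waic: float
    reduced_waic: float
    full_model_better: bool

    @property
    def verdict(self) -> str:
        if self.full_model_better:
            return "sensorimotor variables add predictive power"
        return "no evidence that sensorimotor variables add predictive power"


def compare_models(full: WAICResult, reduced: WAICResult) -> ComparisonVerdict:
    """Full-versus-reduced WAIC comparison on the same observations."""
    if full.n_observations != reduced.n_observations:
        raise ValueError(
            f"models score different observation sets "
            f"({full.n_observations} vs {reduced.n_observations})"
        )
    delta = full.waic - reduced.waic
    return ComparisonVerdict(
        delta_waic=delta, full_waic=full.waic, reduced_waic=reduced.waic,
        full_model_better=delta < 0,
    )


def comparison_table(results: dict) -> pd.DataFrame:
    """Assemble the full/reduced WAIC grid (rows: model; columns: statistic).

    ``results`` maps statistic -> (full WAICResult, reduced WAICResult).
    """
    cols = {}
    for stat, (full, reduced) in results.items():
        cols[stat] = [full.waic, reduced.waic]
    return pd.DataFrame(cols, index=["Full Model", "Reduced Model"])


# ---------------------------------------------------------------------------
# convergence diagnostics


def _split_chains(draws: np.ndarray) -> np.ndarray:
    c, s = draws.shape
    half = s // 2
    return np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)


def gelman_rubin(chains, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Accepts either a ChainSet plus a parameter name, or a raw
    (chains, draws) array.  Identical constant chains return exactly 1.0.
    """
    if isinstance(chains, ChainSet):
        if parameter is None:
            raise ValueError("name the parameter to diagnose")
        draws = chains.parameter_draws(parameter)
    else:
        draws = np.asarray(chains, dtype=float)
    if draws.ndim != 2:
        raise ValueError("need a (chains, draws) array")
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    split = _split_chains(draws)
    m, n = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0  # all split halves constant and equal
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains, parameter: str | None = None) -> float:
    """Bulk effective sample size (delegated to arviz)."""
    import arviz as az

    if isinstance(chains, ChainSet):
        if parameter is None:
            raise ValueError("name the parameter to diagnose")
        draws = chains.parameter_draws(parameter)
    else:
        draws = np.asarray(chains, dtype=float)
    return float(az.ess(az.convert_to_dataset(draws[None] if draws.ndim == 1 else draws))["x"])


@dataclass
class DiagnosticsReport:
    psrf: pd.Series
    ess: pd.Series
    converged: bool
    threshold: float = 1.1


def diagnostics_report(chains: ChainSet, threshold: float = 1.1) -> DiagnosticsReport:
    """R-hat and ESS for every regression coefficient plus tau (and sigma2)."""
    params = list(chains.coef_names) + ["tau"]
    if chains.sigma2 is not None:
        params.append("sigma2")
    psrf = pd.Series({p: gelman_rubin(chains, p) for p in params})
    ess = pd.Series({p: effective_sample_size(chains, p) for p in params})
    return DiagnosticsReport(
        psrf=psrf, ess=ess, converged=bool((psrf < threshold).all()), threshold=threshold
    )


# ---------------------------------------------------------------------------
# posterior predictive checks


@dataclass
class PPCResult:
    p_value: float
    discrepancy: str
    observed: np.ndarray   # realized discrepancy per draw, D(y, theta_s)
    replicated: np.ndarray  # D(y_rep_s, theta_s)


def _disc_max_league_error(y, n, p_or_mu, li, n_leagues, family):
    obs_rate = y / n if family == "binomial" else y
    exp_rate = p_or_mu
    err = np.abs(
        np.bincount(li, weights=obs_rate - exp_rate, minlength=n_leagues)
        / np.maximum(np.bincount(li, minlength=n_leagues), 1)
    )
    return float(err.max())


def _disc_max_cell_error(y, n, p_or_mu, li, n_leagues, family):
    expected = n * p_or_mu if family == "binomial" else p_or_mu
    observed = y
    return float(np.abs(observed - expected).max())


_DISCREPANCIES = {
    "league_mean": _disc_max_league_error,
    "max_cell_error": _disc_max_cell_error,
}


def posterior_predictive_check(
    chains: ChainSet,
    discrepancy="league_mean",
    n_draws: int = 500,
    seed: int = 0,
) -> PPCResult:
    """Realized-discrepancy posterior predictive check.

    For a thinned subset of posterior draws s, a replicate dataset is
    simulated through the full generative path: a fresh latent layer
    eta_rep ~ Normal(alpha_j + s*gamma_j*A_i, 1/tau_s), then binomial (or
    normal) outcomes.  The discrepancy is evaluated on both the replicate
    and the observed data against the regression-level expectation at
    theta_s, and the report is P(D_rep >= D_obs).  Ties count toward the
    p-value, so a constant discrepancy yields p = 1.0 by convention.
    """
    if callable(discrepancy):
        disc_fn, disc_name = discrepancy, getattr(discrepancy, "__name__", "custom")
    else:
        if discrepancy not in _DISCREPANCIES:
            raise ValueError(
                f"unknown discrepancy {discrepancy!r}; options: {sorted(_DISCREPANCIES)}"
            )
        disc_fn, disc_name = _DISCREPANCIES[discrepancy], discrepancy
    rng = np.random.default_rng(seed)
    y = chains.observations["y"].to_numpy(dtype=float)
    n = chains.observations["n"].to_numpy(dtype=float)
    li = chains.observations["league"].map(
        {lg: i for i, lg in enumerate(chains.leagues)}
    ).to_numpy()
    lin_pred = chains.stacked("lin_pred")
    tau = chains.stacked("tau")
    S = lin_pred.shape[0]
    take = np.linspace(0, S - 1, min(n_draws, S)).astype(int)
    d_obs = np.empty(len(take))
    d_rep = np.empty(len(take))
    sigma2 = chains.stacked("sigma2") if chains.family == "normal" else None
    from scipy.special import expit

    for out_i, s in enumerate(take):
        eta_rep = rng.normal(lin_pred[s], 1.0 / np.sqrt(tau[s]))
        if chains.family == "binomial":
            y_rep = rng.binomial(n.astype(np.int64), expit(eta_rep)).astype(float)
            center = expit(lin_pred[s])
        else:
            center = lin_pred[s]
            y_rep = rng.normal(eta_rep, np.sqrt(sigma2[s] / n))
        d_obs[out_i] = disc_fn(y, n, center, li, len(chains.leagues), chains.family)
        d_rep[out_i] = disc_fn(y_rep, n, center, li, len(chains.leagues), chains.family)
    p_value = float(np.mean(d_rep >= d_obs))
    return PPCResult(p_value=p_value, discrepancy=disc_name,
                     observed=d_obs, replicated=d_rep)


def waic_from_chains(chains: ChainSet) -> WAICResult:
    """Convenience: pointwise log-likelihood then WAIC in one call."""
    return compute_waic(pointwise_loglik(chains))
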