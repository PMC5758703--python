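"""Stage 2: hierarchical latent-ability models fit by Gibbs sampling.

Two response families share one hierarchy.  For rate statistics (OBP, BB%,
K%) the stint outcome is binomial with a logit-normal latent layer:

    y_ij ~ Binomial(N_ij, p_ij)
    logit(p_ij) ~ Normal(alpha_j + s * gamma_j * A_i, 1/tau)
    A_i = x_i' beta

and for the per-opportunity averages (SLG, FIP) the outcome is normal with
sampling variance shrinking in the opportunity count:

    y_ij ~ Normal(mu_ij, sigma^2 / N_ij)
    mu_ij ~ Normal(alpha_j + s * gamma_j * A_i, 1/tau)

The orientation s is +1 except for K% and FIP, where higher ability lowers
the response.  League parameters (alpha_j, gamma_j) carry the concentrated
stage-1 priors; beta has a vague normal prior, tau a gamma prior, sigma^2
an inverse-gamma prior, and any missing standardized covariates carry
independent standard-normal priors and are imputed inside the sampler.

The binomial-logit layer is made conjugate by Pólya-Gamma data
augmentation; an augmentation-free adaptive Metropolis-within-Gibbs update
for the logits is provided as a cross-check (``sampler='mh'``), and the two
must agree — that agreement is part of the test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit, gammaln
from scipy.stats import truncnorm

from .game_statistics import DesignMatrix
from .leagues import LEAGUES, orientation as default_orientation, response_family
from .league_calibration import LeagueCalibration
from .polya_gamma import random_polyagamma

__all__ = [
    "ModelSpec",
    "ChainSet",
    "GibbsSampler",
    "fit_binomial",
    "fit_normal",
    "fit_model",
    "impute_missing_covariates",
    "pointwise_loglik",
]


def _log1pexp(x):
    return np.logaddexp(0.0, x)


def _prepare_observations(df: pd.DataFrame, family: str, restrict_leagues=None,
                          player_index: pd.Index | None = None):
    """Flatten a tidy stint frame into aligned arrays for the sampler."""
    required = {"player_id", "league"}
    required |= {"successes", "trials"} if family == "binomial" else {"value", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation frame lacks columns {sorted(missing)}")
    if family == "binomial":
        y = df["successes"].to_numpy(dtype=float)
        n = df["trials"].to_numpy(dtype=float)
        if np.any((y < 0) | (y > n)):
            raise ValueError("successes must lie in [0, trials]")
    else:
        y = df["value"].to_numpy(dtype=float)
        n = df["weight"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(n))):
        raise ValueError("non-finite observation values")
    if np.any(n <= 0):
        raise ValueError("trials/weights must be positive")

    if restrict_leagues is not None:
        leagues = list(restrict_leagues)
        unknown = set(df["league"]) - set(leagues)
        if unknown:
            raise ValueError(
                f"leagues {sorted(unknown)} absent from the calibration {leagues}"
            )
    else:
        leagues = sorted(df["league"].unique(), key=LEAGUES.index)
    lg_idx = {lg: i for i, lg in enumerate(leagues)}
    li = df["league"].map(lg_idx).to_numpy(dtype=np.intp)

    if player_index is None:
        player_index = pd.Index(pd.unique(df["player_id"]))
    else:
        unknown = set(df["player_id"]) - set(player_index)
        if unknown:
            raise ValueError(f"observed players missing from design matrix: {sorted(unknown)[:5]}")
    p_idx = {p: i for i, p in enumerate(player_index)}
    pi = df["player_id"].map(p_idx).to_numpy(dtype=np.intp)
    return y, n, pi, li, player_index, leagues


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Everything needed to fit one statistic's stage-2 model.

    ``covariate_set`` 'full' uses the sensorimotor design; 'reduced' keeps
    only intercept, age and (for batters) the position dummies — the same
    code path, smaller matrix.  ``league_params`` 'sampled' draws alpha_j,
    gamma_j under their concentrated priors; 'fixed' pins them at the prior
    means.  ``overdispersed=False`` collapses the latent layer (tau^-1 = 0),
    which makes the normal-family posterior for beta exactly conjugate.
    """

    statistic: str
    calibration: LeagueCalibration
    covariate_set: str = "full"
    response_family: str | None = None
    orientation: int | None = None
    prior_beta_var: float = 100.0
    prior_tau: tuple[float, float] = (0.001, 0.001)
    prior_sigma2: tuple[float, float] = (0.001, 0.001)
    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 1_000
    seed: int = 0
    sampler: str = "pg"
    league_params: str = "sampled"
    overdispersed: bool = True
    fix_tau: float | None = None
    pg_trunc: int = 100

    def __post_init__(self) -> None:
        if self.response_family is None:
            self.response_family = response_family(self.statistic)
        if self.orientation is None:
            self.orientation = default_orientation(self.statistic)
        if self.orientation not in (+1, -1):
            raise ValueError("orientation must be +1 or -1")
        if self.covariate_set not in ("full", "reduced"):
            raise ValueError("covariate_set must be 'full' or 'reduced'")
        if self.sampler not in ("pg", "mh"):
            raise ValueError("sampler must be 'pg' or 'mh'")
        if self.league_params not in ("sampled", "fixed"):
            raise ValueError("league_params must be 'sampled' or 'fixed'")
        if self.calibration.statistic != self.statistic:
            raise ValueError(
                f"calibration is for {self.calibration.statistic!r}, spec for {self.statistic!r}"
            )

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "calibration"}
        d["calibration_provenance"] = self.calibration.provenance
        return d


# ---------------------------------------------------------------------------
# the Gibbs sampler


class GibbsSampler:
    """Systematic-scan Gibbs sampler state for the latent-ability hierarchy.

    ``mode='regression'`` ties abilities to covariates (A = X beta, stage 2);
    ``mode='free'`` gives every player a free ability with a standard-normal
    prior (stage-1 league calibration).  All update methods operate in place;
    ``sweep`` runs one full scan.
    """

    def __init__(
        self, *, y, n, player_index, league_index, n_players, family, orientation,
        alpha0, alpha_sd, gamma0, gamma_sd,
        X=None, missing_entries=None, mode="regression",
        prior_beta_var=100.0, prior_tau=(0.001, 0.001), prior_sigma2=(0.001, 0.001),
        fix_tau=None, overdispersed=True, sampler="pg", pg_trunc=100, rng=None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.pi = np.asarray(player_index, dtype=np.intp)
        self.li = np.asarray(league_index, dtype=np.intp)
        self.n_obs = len(self.y)
        self.n_players = int(n_players)
        self.n_leagues = len(alpha0)
        self.family = family
        self.s = int(orientation)
        self.mode = mode
        self.alpha0 = np.asarray(alpha0, dtype=float)
        self.alpha_sd = np.asarray(alpha_sd, dtype=float)
        self.gamma0 = np.asarray(gamma0, dtype=float)
        self.gamma_sd = np.asarray(gamma_sd, dtype=float)
        self.prior_beta_var = float(prior_beta_var)
        self.prior_tau = tuple(prior_tau)
        self.prior_sigma2 = tuple(prior_sigma2)
        self.fix_tau = fix_tau
        self.overdispersed = bool(overdispersed)
        self.sampler = sampler
        self.pg_trunc = int(pg_trunc)
        self.rng = rng if rng is not None else np.random.default_rng()

        if mode == "regression":
            if X is None:
                raise ValueError("regression mode needs a design matrix")
            self.x = np.array(X, dtype=float)
            self.p = self.x.shape[1]
            self.beta = np.zeros(self.p)
            self.missing_entries = list(missing_entries or [])
            # observation rows per player with a missing covariate
            self._obs_of_player = {
                i: np.flatnonzero(self.pi == i)
                for i in sorted({i for i, _ in self.missing_entries})
            }
        elif mode == "free":
            self.ability = np.zeros(self.n_players)
            self.missing_entries = []
        else:
            raise ValueError("mode must be 'regression' or 'free'")

        self.alpha = self.alpha0.copy()
        self.gamma = np.maximum(self.gamma0, 1e-6)
        self.tau = float(fix_tau) if fix_tau is not None else 1.0
        if family == "normal":
            v = float(np.var(self.y))
            self.sigma2 = v if v > 0 else 1.0
        else:
            self.sigma2 = None
            self.kappa = self.y - self.n / 2.0

        self._refresh_ability()
        if family == "binomial":
            self.eta = np.log((self.y + 0.5) / (self.n - self.y + 0.5))
        else:
            self.eta = self.y.copy()
        if not self.overdispersed:
            self.eta = self.linear_predictor()
        self.mh_step = np.full(self.n_obs, 0.5)

    # -- helpers ------------------------------------------------------------

    def _refresh_ability(self) -> None:
        if self.mode == "regression":
            self.A = self.x @ self.beta
        else:
            self.A = self.ability

    def linear_predictor(self) -> np.ndarray:
        return self.alpha[self.li] + self.s * self.gamma[self.li] * self.A[self.pi]

    def set_response(self, y) -> None:
        self.y = np.asarray(y, dtype=float)
        if self.family == "binomial":
            self.kappa = self.y - self.n / 2.0

    def simulate_response(self) -> np.ndarray:
        """Draw a replicate outcome vector from the current latent state."""
        if self.family == "binomial":
            return self.rng.binomial(self.n.astype(np.int64), expit(self.eta)).astype(float)
        return self.rng.normal(self.eta, np.sqrt(self.sigma2 / self.n))

    # -- response layer -----------------------------------------------------

    def _update_latent_layer(self, adapt: bool) -> tuple[np.ndarray, np.ndarray]:
        """Refresh the latent logits/means; return pseudo-response and weights.

        Every remaining conditional is a weighted-normal update of the form
        r ~ Normal(linear predictor, 1/w) elementwise; this method hides the
        family- and augmentation-specific bookkeeping behind that (r, w).
        """
        m = self.linear_predictor()
        if not self.overdispersed:
            self.eta = m
            if self.family == "binomial":
                omega = random_polyagamma(self.n, self.eta, self.rng, self.pg_trunc)
                omega = np.maximum(omega, 1e-12)
                return self.kappa / omega, omega
            return self.y, self.n / self.sigma2
        if self.family == "binomial":
            if self.sampler == "pg":
                omega = random_polyagamma(self.n, self.eta, self.rng, self.pg_trunc)
                prec = omega + self.tau
                mean = (self.kappa + self.tau * m) / prec
                self.eta = mean + self.rng.standard_normal(self.n_obs) / np.sqrt(prec)
            else:
                self._mh_eta(m, adapt)
        else:
            prec = self.n / self.sigma2 + self.tau
            mean = (self.n * self.y / self.sigma2 + self.tau * m) / prec
            self.eta = mean + self.rng.standard_normal(self.n_obs) / np.sqrt(prec)
        return self.eta, np.full(self.n_obs, self.tau)

    def _mh_eta(self, m: np.ndarray, adapt: bool) -> None:
        prop = self.eta + self.mh_step * self.rng.standard_normal(self.n_obs)
        def logpost(e):
            return self.y * e - self.n * _log1pexp(e) - 0.5 * self.tau * (e - m) ** 2
        log_ratio = logpost(prop) - logpost(self.eta)
        accept = np.log(self.rng.random(self.n_obs)) < log_ratio
        self.eta = np.where(accept, prop, self.eta)
        if adapt:
            # nudge per-observation step sizes toward ~30% acceptance
            self.mh_step *= np.exp(0.08 * (accept.astype(float) - 0.3))
            np.clip(self.mh_step, 1e-3, 10.0, out=self.mh_step)

    # -- regression-mode updates --------------------------------------------

    def _update_beta(self, r, w) -> None:
        mean, chol_prec = self._beta_moments(r, w)
        z = self.rng.standard_normal(self.p)
        self.beta = mean + solve_triangular(chol_prec.T, z, lower=False)
        self._refresh_ability()

    def _beta_moments(self, r, w):
        d = (self.s * self.gamma[self.li])[:, None] * self.x[self.pi]
        resp = r - self.alpha[self.li]
        prec = np.eye(self.p) / self.prior_beta_var + d.T @ (w[:, None] * d)
        chol = np.linalg.cholesky(prec)
        rhs = d.T @ (w * resp)
        mean = cho_solve((chol, True), rhs)
        return mean, chol

    def beta_conditional(self, r=None, w=None):
        """Mean and covariance of the current beta full conditional.

        With ``overdispersed=False`` in the normal family this conditional
        is the exact weighted-Bayes-regression posterior of beta given
        fixed league parameters.
        """
        if r is None:
            if self.overdispersed:
                r, w = self.eta, np.full(self.n_obs, self.tau)
            elif self.family == "normal":
                r, w = self.y, self.n / self.sigma2
            else:
                raise ValueError("collapsed binomial conditional depends on the PG draw")
        mean, chol = self._beta_moments(r, np.asarray(w, dtype=float))
        cov = cho_solve((chol, True), np.eye(self.p))
        return mean, cov

    def impute_missing(self, r=None, w=None, return_moments: bool = False):
        """Gibbs update of missing standardized covariates.

        Each missing entry has an independent N(0, 1) prior; given the
        latent layer the likelihood is linear in the entry, so the full
        conditional is a conjugate normal.  Players with no surviving
        observations draw from the prior alone.
        """
        if r is None:
            if not self.overdispersed:
                raise ValueError("pass (r, w) explicitly in collapsed mode")
            r, w = self.eta, np.full(self.n_obs, self.tau)
        w = np.asarray(w, dtype=float)
        moments = {}
        for (i, k) in self.missing_entries:
            obs = self._obs_of_player.get(i, np.empty(0, dtype=np.intp))
            beta_k = self.beta[k]
            contrib = beta_k * self.x[i, k]
            c = self.A[i] - contrib
            if len(obs) == 0 or beta_k == 0.0:
                mean, var = 0.0, 1.0
            else:
                g = self.s * self.gamma[self.li[obs]]
                u = g * beta_k
                resid = r[obs] - self.alpha[self.li[obs]] - g * c
                prec = 1.0 + np.sum(w[obs] * u * u)
                mean = np.sum(w[obs] * u * resid) / prec
                var = 1.0 / prec
            draw = mean + np.sqrt(var) * self.rng.standard_normal()
            self.x[i, k] = draw
            self.A[i] = c + beta_k * draw
            moments[(i, k)] = (mean, var)
        if return_moments:
            return moments

    # -- free-ability update (stage 1) --------------------------------------

    def _update_ability(self, r, w) -> None:
        u = self.s * self.gamma[self.li]
        resid = r - self.alpha[self.li]
        quad = np.bincount(self.pi, weights=w * u * u, minlength=self.n_players)
        lin = np.bincount(self.pi, weights=w * u * resid, minlength=self.n_players)
        prec = 1.0 + quad  # N(0,1) prior pins the ability scale
        mean = lin / prec
        self.ability = mean + self.rng.standard_normal(self.n_players) / np.sqrt(prec)
        self.A = self.ability

    # -- league parameters ---------------------------------------------------

    def _update_alpha(self, r, w) -> None:
        free = self.alpha_sd > 0
        if not np.any(free):
            return
        resid = r - self.s * self.gamma[self.li] * self.A[self.pi]
        n_w = np.bincount(self.li, weights=w, minlength=self.n_leagues)
        s_wr = np.bincount(self.li, weights=w * resid, minlength=self.n_leagues)
        prior_prec = np.zeros(self.n_leagues)
        prior_prec[free] = 1.0 / self.alpha_sd[free] ** 2
        prec = prior_prec + n_w
        mean = (prior_prec * self.alpha0 + s_wr) / np.maximum(prec, 1e-300)
        draw = mean + self.rng.standard_normal(self.n_leagues) / np.sqrt(np.maximum(prec, 1e-300))
        self.alpha = np.where(free, draw, self.alpha)

    def _update_gamma(self, r, w) -> None:
        free = self.gamma_sd > 0
        if not np.any(free):
            return
        t = self.s * self.A[self.pi]
        resid = r - self.alpha[self.li]
        quad = np.bincount(self.li, weights=w * t * t, minlength=self.n_leagues)
        lin = np.bincount(self.li, weights=w * t * resid, minlength=self.n_leagues)
        prior_prec = np.zeros(self.n_leagues)
        prior_prec[free] = 1.0 / self.gamma_sd[free] ** 2
        prec = np.maximum(prior_prec + quad, 1e-300)
        mean = (prior_prec * self.gamma0 + lin) / prec
        sd = 1.0 / np.sqrt(prec)
        idx = np.flatnonzero(free)
        a = (0.0 - mean[idx]) / sd[idx]  # truncate at gamma > 0
        draw = truncnorm.rvs(a, np.inf, loc=mean[idx], scale=sd[idx], random_state=self.rng)
        self.gamma[idx] = np.atleast_1d(draw)

    # -- dispersion parameters -----------------------------------------------

    def _update_tau(self) -> None:
        resid = self.eta - self.linear_predictor()
        a0, b0 = self.prior_tau
        shape = a0 + 0.5 * self.n_obs
        rate = b0 + 0.5 * float(resid @ resid)
        self.tau = self.rng.gamma(shape, 1.0 / rate)

    def _update_sigma2(self) -> None:
        resid = self.y - self.eta
        a0, b0 = self.prior_sigma2
        shape = a0 + 0.5 * self.n_obs
        rate = b0 + 0.5 * float(np.sum(self.n * resid**2))
        self.sigma2 = 1.0 / self.rng.gamma(shape, 1.0 / rate)

    # -- prior simulation (used by joint-distribution correctness tests) -----

    def draw_from_priors(self) -> None:
        if self.mode == "regression":
            self.beta = self.rng.normal(0.0, np.sqrt(self.prior_beta_var), self.p)
            for (i, k) in self.missing_entries:
                self.x[i, k] = self.rng.standard_normal()
        else:
            self.ability = self.rng.standard_normal(self.n_players)
        free_a = self.alpha_sd > 0
        self.alpha = np.where(
            free_a, self.rng.normal(self.alpha0, np.where(free_a, self.alpha_sd, 1.0)), self.alpha0
        )
        free_g = self.gamma_sd > 0
        gam = self.gamma0.astype(float).copy()
        if np.any(free_g):
            idx = np.flatnonzero(free_g)
            a = (0.0 - self.gamma0[idx]) / self.gamma_sd[idx]
            gam[idx] = np.atleast_1d(
                truncnorm.rvs(a, np.inf, loc=self.gamma0[idx], scale=self.gamma_sd[idx],
                              random_state=self.rng)
            )
        self.gamma = np.maximum(gam, 1e-12)
        if self.fix_tau is None:
            a0, b0 = self.prior_tau
            self.tau = self.rng.gamma(a0, 1.0 / b0)
        if self.family == "normal":
            a0, b0 = self.prior_sigma2
            self.sigma2 = 1.0 / self.rng.gamma(a0, 1.0 / b0)
        self._refresh_ability()
        m = self.linear_predictor()
        if self.overdispersed:
            self.eta = self.rng.normal(m, 1.0 / np.sqrt(self.tau))
        else:
            self.eta = m

    # -- one systematic scan --------------------------------------------------

    def sweep(self, adapt: bool = False) -> None:
        r, w = self._update_latent_layer(adapt)
        if self.mode == "regression":
            self._update_beta(r, w)
            if self.missing_entries:
                self.impute_missing(r, w)
        else:
            self._update_ability(r, w)
        self._update_gamma(r, w)
        self._update_alpha(r, w)
        if self.overdispersed and self.fix_tau is None:
            self._update_tau()
        if self.family == "normal":
            self._update_sigma2()


def impute_missing_covariates(state: GibbsSampler, return_moments: bool = False):
    """Run the missing-covariate Gibbs step on a sampler state (test hook)."""
    return state.impute_missing(return_moments=return_moments)


# ---------------------------------------------------------------------------
# chain container


@dataclass
class ChainSet:
    """Posterior draws across chains, post burn-in.

    ``eta`` holds the per-observation latent linear predictors: the logit of
    p_ij for binomial fits, mu_ij for normal fits.
    """

    beta: np.ndarray            # (chains, draws, p)
    tau: np.ndarray             # (chains, draws)
    alpha: np.ndarray           # (chains, draws, L)
    gamma: np.ndarray           # (chains, draws, L)
    eta: np.ndarray             # (chains, draws, n_obs)
    lin_pred: np.ndarray        # (chains, draws, n_obs): alpha_j + s*gamma_j*A_i
    sigma2: np.ndarray | None   # (chains, draws) for the normal family
    imputed: np.ndarray | None  # (chains, draws, n_missing)
    imputed_entries: list       # [(player_id, coefficient), ...]
    coef_names: tuple
    leagues: tuple
    observations: pd.DataFrame  # player_id, league, y, n
    family: str
    orientation: int
    statistic: str
    spec_echo: dict = field(default_factory=dict)
    seeds: tuple = ()

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} draws not present")
        return arr.reshape(-1, *arr.shape[2:])

    def coefficient_draws(self) -> pd.DataFrame:
        return pd.DataFrame(self.stacked("beta"), columns=list(self.coef_names))

    def parameter_draws(self, parameter: str) -> np.ndarray:
        """Per-chain draws (chains, draws) for a named scalar parameter."""
        if parameter == "tau":
            return self.tau
        if parameter == "sigma2":
            if self.sigma2 is None:
                raise ValueError("no sigma2 draws in a binomial fit")
            return self.sigma2
        if parameter in self.coef_names:
            return self.beta[:, :, self.coef_names.index(parameter)]
        if parameter.startswith("alpha:"):
            return self.alpha[:, :, self.leagues.index(parameter.split(":", 1)[1])]
        if parameter.startswith("gamma:"):
            return self.gamma[:, :, self.leagues.index(parameter.split(":", 1)[1])]
        raise KeyError(f"unknown parameter {parameter!r}")

    def save(self, path) -> None:
        """Write draws as CSV with a '#'-prefixed YAML metadata header."""
        import yaml

        meta = {
            "statistic": self.statistic, "family": self.family,
            "orientation": self.orientation, "coef_names": list(self.coef_names),
            "leagues": list(self.leagues), "spec": _jsonable(self.spec_echo),
            "seeds": list(self.seeds),
            "imputed_entries": [list(map(str, e)) for e in self.imputed_entries],
            "observations": self.observations.to_dict("list"),
        }
        cols = {}
        for j, name in enumerate(self.coef_names):
            cols[f"beta:{name}"] = self.beta[:, :, j].reshape(-1)
        cols["tau"] = self.tau.reshape(-1)
        if self.sigma2 is not None:
            cols["sigma2"] = self.sigma2.reshape(-1)
        for j, lg in enumerate(self.leagues):
            cols[f"alpha:{lg}"] = self.alpha[:, :, j].reshape(-1)
            cols[f"gamma:{lg}"] = self.gamma[:, :, j].reshape(-1)
        for j in range(self.eta.shape[2]):
            cols[f"eta:{j}"] = self.eta[:, :, j].reshape(-1)
            cols[f"m:{j}"] = self.lin_pred[:, :, j].reshape(-1)
        if self.imputed is not None:
            for j, entry in enumerate(self.imputed_entries):
                cols[f"imputed:{entry[0]}:{entry[1]}"] = self.imputed[:, :, j].reshape(-1)
        frame = pd.DataFrame(cols)
        frame.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.beta.shape[1]))
        frame.insert(1, "iteration", np.tile(np.arange(self.beta.shape[1]), self.n_chains))
        with open(path, "w") as fh:
            header = yaml.safe_dump(meta, sort_keys=False)
            fh.write("".join(f"# {line}\n" for line in header.splitlines()))
            frame.to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "ChainSet":
        import yaml

        header_lines = []
        with open(path) as fh:
            body = []
            for line in fh:
                if line.startswith("# "):
                    header_lines.append(line[2:])
                elif line.startswith("#"):
                    header_lines.append(line[1:])
                else:
                    body.append(line)
        meta = yaml.safe_load("".join(header_lines))
        frame = pd.read_csv(io.StringIO("".join(body)))
        chains = int(frame["chain"].max()) + 1
        draws = int(frame["iteration"].max()) + 1

        def grab(prefix, names):
            return np.stack(
                [frame[f"{prefix}:{nm}"].to_numpy().reshape(chains, draws) for nm in names],
                axis=2,
            )

        coef_names = tuple(meta["coef_names"])
        leagues = tuple(meta["leagues"])
        eta_cols = sorted(
            (c for c in frame.columns if c.startswith("eta:")), key=lambda c: int(c.split(":")[1])
        )
        eta = np.stack([frame[c].to_numpy().reshape(chains, draws) for c in eta_cols], axis=2)
        m_cols = [c.replace("eta:", "m:") for c in eta_cols]
        lin_pred = np.stack([frame[c].to_numpy().reshape(chains, draws) for c in m_cols], axis=2)
        imputed_entries = [tuple(e) for e in meta.get("imputed_entries", [])]
        imp_cols = [c for c in frame.columns if c.startswith("imputed:")]
        imputed = (
            np.stack([frame[c].to_numpy().reshape(chains, draws) for c in imp_cols], axis=2)
            if imp_cols else None
        )
        return cls(
            beta=grab("beta", coef_names),
            tau=frame["tau"].to_numpy().reshape(chains, draws),
            alpha=grab("alpha", leagues),
            gamma=grab("gamma", leagues),
            eta=eta,
            lin_pred=lin_pred,
            sigma2=(frame["sigma2"].to_numpy().reshape(chains, draws)
                    if "sigma2" in frame.columns else None),
            imputed=imputed,
            imputed_entries=imputed_entries,
            coef_names=coef_names,
            leagues=leagues,
            observations=pd.DataFrame(meta["observations"]),
            family=meta["family"],
            orientation=int(meta["orientation"]),
            statistic=meta["statistic"],
            spec_echo=meta.get("spec", {}),
            seeds=tuple(meta.get("seeds", ())),
        )


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# fitting


def make_sampler(observations: pd.DataFrame, design: DesignMatrix, spec: ModelSpec,
                 rng: np.random.Generator | None = None) -> GibbsSampler:
    """Build a ready-to-sweep Gibbs state (also the entry point for the
    joint-distribution correctness tests, which drive sweeps directly)."""
    if spec.covariate_set == "reduced":
        design = design.reduced()
    cal = spec.calibration
    y, n, pi, li, player_index, leagues = _prepare_observations(
        observations, spec.response_family, restrict_leagues=cal.leagues,
        player_index=design.player_ids,
    )
    mask = design.missing_mask.to_numpy()
    missing_entries = [(int(i), int(k)) for i, k in zip(*np.nonzero(mask))]
    alpha_sd = cal.alpha_sd.to_numpy(dtype=float)
    gamma_sd = cal.gamma_sd.to_numpy(dtype=float)
    if spec.league_params == "fixed":
        alpha_sd = np.zeros_like(alpha_sd)
        gamma_sd = np.zeros_like(gamma_sd)
    return GibbsSampler(
        y=y, n=n, player_index=pi, league_index=li, n_players=len(player_index),
        family=spec.response_family, orientation=spec.orientation,
        alpha0=cal.alpha_mean.to_numpy(dtype=float), alpha_sd=alpha_sd,
        gamma0=cal.gamma_mean.to_numpy(dtype=float), gamma_sd=gamma_sd,
        X=design.X.to_numpy(dtype=float), missing_entries=missing_entries,
        mode="regression", prior_beta_var=spec.prior_beta_var,
        prior_tau=spec.prior_tau, prior_sigma2=spec.prior_sigma2,
        fix_tau=spec.fix_tau, overdispersed=spec.overdispersed,
        sampler=spec.sampler, pg_trunc=spec.pg_trunc, rng=rng,
    )


def fit_model(observations: pd.DataFrame, design: DesignMatrix, spec: ModelSpec) -> ChainSet:
    """Run the Gibbs sampler for one statistic and return post-burn-in draws."""
    if spec.covariate_set == "reduced":
        design_used = design.reduced()
    else:
        design_used = design
    cal = spec.calibration
    y, n, pi, li, player_index, leagues = _prepare_observations(
        observations, spec.response_family, restrict_leagues=cal.leagues,
        player_index=design_used.player_ids,
    )
    mask = design_used.missing_mask.to_numpy()
    entry_rows = list(zip(*np.nonzero(mask)))
    entries_named = [
        (str(design_used.player_ids[i]), design_used.columns[k]) for i, k in entry_rows
    ]
    C, S = spec.chains, spec.iterations
    p = len(design_used.columns)
    L = len(cal.leagues)
    beta = np.empty((C, S, p))
    tau = np.empty((C, S))
    alpha = np.empty((C, S, L))
    gamma = np.empty((C, S, L))
    eta = np.empty((C, S, len(y)))
    lin_pred = np.empty((C, S, len(y)))
    sigma2 = np.empty((C, S)) if spec.response_family == "normal" else None
    imputed = np.empty((C, S, len(entry_rows))) if entry_rows else None
    seeds = []
    for c in range(C):
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(c,))
        seeds.append(int(ss.generate_state(1)[0]))
        rng = np.random.default_rng(ss)
        state = make_sampler(observations, design, spec, rng=rng)
        for _ in range(spec.burn_in):
            state.sweep(adapt=True)
        for t in range(S):
            state.sweep()
            beta[c, t] = state.beta
            tau[c, t] = state.tau
            alpha[c, t] = state.alpha
            gamma[c, t] = state.gamma
            eta[c, t] = state.eta
            lin_pred[c, t] = state.linear_predictor()
            if sigma2 is not None:
                sigma2[c, t] = state.sigma2
            if imputed is not None:
                imputed[c, t] = [state.x[i, k] for i, k in entry_rows]
    obs_frame = pd.DataFrame(
        {
            "player_id": observations["player_id"].astype(str).tolist(),
            "league": observations["league"].tolist(),
            "y": y.tolist(),
            "n": n.tolist(),
        }
    )
    return ChainSet(
        beta=beta, tau=tau, alpha=alpha, gamma=gamma, eta=eta,
        lin_pred=lin_pred, sigma2=sigma2,
        imputed=imputed, imputed_entries=entries_named,
        coef_names=tuple(design_used.columns), leagues=tuple(cal.leagues),
        observations=obs_frame, family=spec.response_family,
        orientation=spec.orientation, statistic=spec.statistic,
        spec_echo=spec.echo(), seeds=tuple(seeds),
    )


def fit_binomial(observations: pd.DataFrame, design: DesignMatrix, spec: ModelSpec) -> ChainSet:
    """Fit the binomial-logit hierarchy (OBP, BB%, K%)."""
    if spec.response_family != "binomial":
        raise ValueError(f"spec family is {spec.response_family!r}, expected 'binomial'")
    return fit_model(observations, design, spec)


def fit_normal(observations: pd.DataFrame, design: DesignMatrix, spec: ModelSpec) -> ChainSet:
    """Fit the weighted-normal hierarchy (SLG, FIP)."""
    if spec.response_family != "normal":
        raise ValueError(f"spec family is {spec.response_family!r}, expected 'normal'")
    return fit_model(observations, design, spec)


# ---------------------------------------------------------------------------
# pointwise log-likelihood (feeds WAIC)


def pointwise_loglik(chains: ChainSet, observations: pd.DataFrame | None = None) -> np.ndarray:
    """Draws x observations matrix of log p(y_ij | draw), the WAIC input.

    Binomial entries are log Binomial(y | N, inv-logit(eta^(s))); normal
    entries are log Normal(y | mu^(s), sigma2^(s)/N).
    """
    y = chains.observations["y"].to_numpy(dtype=float)
    n = chains.observations["n"].to_numpy(dtype=float)
    if observations is not None and len(observations) != len(y):
        raise ValueError(
            f"observation count mismatch: chains carry {len(y)}, got {len(observations)}"
        )
    eta = chains.stacked("eta")  # (S, n_obs)
    if chains.family == "binomial":
        const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        return const + y * eta - n * _log1pexp(eta)
    sigma2 = chains.stacked("sigma2")[:, None]
    var = sigma2 / n
    return -0.5 * (np.log(2.0 * np.pi * var) + (y - eta) ** 2 / var)
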