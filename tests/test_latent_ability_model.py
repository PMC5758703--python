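"""Gibbs-sampler correctness: conjugate oracles, degenerate limits, and a
joint-distribution (marginal- vs successive-conditional) simulation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from conftest import make_calibration, make_design
from senseball.latent_ability_model import (
    ChainSet,
    GibbsSampler,
    ModelSpec,
    fit_binomial,
    fit_model,
    fit_normal,
    impute_missing_covariates,
    make_sampler,
    pointwise_loglik,
)
from senseball.polya_gamma import pg_mean, pg_var, random_polyagamma


class TestPolyaGamma:
    @pytest.mark.parametrize("b, z", [(1.0, 0.0), (1.0, 2.5), (40.0, 0.7), (300.0, -1.2)])
    def test_moments_match_analytic(self, b, z):
        rng = np.random.default_rng(0)
        draws = random_polyagamma(np.full(20_000, b), np.full(20_000, z), rng)
        se = np.sqrt(pg_var(b, z) / draws.size)
        assert draws.mean() == pytest.approx(float(pg_mean(b, z)), abs=5 * se)
        assert draws.var() == pytest.approx(float(pg_var(b, z)), rel=0.05)

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError):
            random_polyagamma(0.0, 1.0, np.random.default_rng(0))


def _toy_binomial_obs(successes, trials, leagues=("MLB",), players=None):
    players = players or [f"P{i}" for i in range(len(successes))]
    lg = list(leagues) * (len(successes) // len(leagues) + 1)
    return pd.DataFrame({
        "player_id": players, "league": lg[: len(successes)],
        "successes": successes, "trials": trials,
    })


class TestBinomialFit:
    def test_zero_gamma_returns_the_prior(self):
        """With gamma pinned at (numerically) zero no likelihood reaches beta,
        so its draws must be indistinguishable from the N(0, v) prior."""
        cal = make_calibration(gamma=(1e-12,))
        obs = _toy_binomial_obs([40, 60, 55], [100, 120, 130])
        X = pd.DataFrame({"x": [0.3, -1.2, 0.7]},
                         index=pd.Index(["P0", "P1", "P2"], name="player_id"))
        spec = ModelSpec("OBP", cal, chains=1, iterations=10_000, burn_in=100,
                         prior_beta_var=4.0, seed=0)
        chains = fit_binomial(obs, make_design(X), spec)
        draws = chains.stacked("beta")[:, 0]
        prior = np.random.default_rng(1).normal(0, 2.0, 10_000)
        ks = stats.ks_2samp(draws, prior).statistic
        assert ks < 0.05

    def test_unknown_league_rejected(self):
        cal = make_calibration(leagues=("MLB",))
        obs = _toy_binomial_obs([40], [100])
        obs["league"] = "Rookie"
        X = pd.DataFrame({"x": [0.0]}, index=pd.Index(["P0"], name="player_id"))
        with pytest.raises(ValueError, match="absent from the calibration"):
            fit_binomial(obs, make_design(X), ModelSpec("OBP", cal, chains=1,
                         iterations=10, burn_in=1))

    def test_non_finite_input_rejected(self):
        cal = make_calibration()
        obs = _toy_binomial_obs([40], [100]).assign(successes=[np.nan])
        X = pd.DataFrame({"x": [0.0]}, index=pd.Index(["P0"], name="player_id"))
        with pytest.raises(ValueError, match="non-finite"):
            fit_binomial(obs, make_design(X), ModelSpec("OBP", cal, chains=1,
                         iterations=10, burn_in=1))


class TestNormalFit:
    def _setup(self):
        rng = np.random.default_rng(8)
        n_players = 12
        ids = pd.Index([f"P{i}" for i in range(n_players)], name="player_id")
        X = pd.DataFrame({"intercept": 1.0, "x": rng.standard_normal(n_players)},
                         index=ids)
        cal = make_calibration("SLG", alpha=(0.35,), gamma=(0.05,))
        w = rng.integers(40, 300, n_players).astype(float)
        beta = np.array([0.5, -0.8])
        y = 0.35 + 0.05 * (X.to_numpy() @ beta) + rng.normal(0, np.sqrt(0.36 / w))
        obs = pd.DataFrame({"player_id": ids, "league": "MLB", "value": y, "weight": w})
        return obs, X, cal

    def test_collapsed_conditional_is_the_weighted_bayes_posterior(self):
        """tau^-1 = 0: the beta full conditional equals the closed-form
        weighted Bayes regression posterior (independent assembly)."""
        obs, X, cal = self._setup()
        spec = ModelSpec("SLG", cal, chains=1, iterations=10, burn_in=0,
                         overdispersed=False, prior_beta_var=9.0, seed=0)
        state = make_sampler(obs, make_design(X), spec,
                             rng=np.random.default_rng(0))
        state.sigma2 = 0.36  # known sampling variance
        mean, cov = state.beta_conditional()
        # oracle: regression of (y - alpha) on gamma * X with weights N/sigma^2
        D = 0.05 * X.to_numpy()
        resp = obs["value"].to_numpy() - 0.35
        o_mean, o_cov = oracles.conjugate_weighted_regression(
            resp, D, obs["weight"].to_numpy() / 0.36, prior_var=9.0
        )
        np.testing.assert_allclose(mean, o_mean, rtol=1e-6)
        np.testing.assert_allclose(cov, o_cov, rtol=1e-6)

    def test_sigma2_concentrates_on_noiseless_data(self):
        obs, X, cal = self._setup()
        obs = obs.copy()
        obs["value"] = 0.35  # constant response, zero noise, gamma ~ 0
        cal = make_calibration("SLG", alpha=(0.35,), gamma=(1e-12,))
        spec = ModelSpec("SLG", cal, chains=1, iterations=2000, burn_in=500,
                         overdispersed=False, seed=1)
        chains = fit_normal(obs, make_design(X), spec)
        assert np.median(chains.stacked("sigma2")) < 1e-3
        assert (chains.stacked("sigma2") > 0).all()

    def test_observation_order_is_irrelevant(self):
        obs, X, cal = self._setup()
        spec = ModelSpec("SLG", cal, chains=2, iterations=1500, burn_in=500, seed=3)
        a = fit_normal(obs, make_design(X), spec)
        b = fit_normal(obs.iloc[::-1].reset_index(drop=True), make_design(X), spec)
        ma, mb = a.coefficient_draws().mean(), b.coefficient_draws().mean()
        sd = a.coefficient_draws().std()
        assert np.all(np.abs(ma - mb) < 0.25 * sd + 0.02)

    def test_family_mismatch_rejected(self):
        obs, X, cal = self._setup()
        with pytest.raises(ValueError, match="binomial"):
            fit_binomial(obs, make_design(X),
                         ModelSpec("SLG", cal, chains=1, iterations=10, burn_in=1))


class TestImputation:
    def _state(self, with_obs=True):
        cal = make_calibration(alpha=(-0.8,), gamma=(0.5,))
        ids = pd.Index(["P0", "P1"], name="player_id")
        X = pd.DataFrame({"intercept": [1.0, 1.0], "x": [0.4, 0.0]}, index=ids)
        obs = _toy_binomial_obs([40, 50], [100, 120], players=["P0", "P0"]) \
            if with_obs else _toy_binomial_obs([40], [100], players=["P0"])
        design = make_design(X, missing=[("P1", "x")] if not with_obs else [("P0", "x")])
        spec = ModelSpec("OBP", cal, chains=1, iterations=10, burn_in=0, seed=0)
        return make_sampler(obs, design, spec, rng=np.random.default_rng(7))

    def test_prior_only_draw_for_unobserved_player(self):
        """A player outside the analyzed pool still gets a draw: exactly N(0,1)."""
        state = self._state(with_obs=False)  # P1 has the hole, but no stints
        moments = impute_missing_covariates(state, return_moments=True)
        (mean, var), = moments.values()
        assert mean == 0.0 and var == 1.0

    def test_zero_coefficient_reduces_to_the_prior(self):
        state = self._state(with_obs=True)
        state.beta = np.array([0.1, 0.0])  # coefficient of the missing column
        state._refresh_ability()
        moments = impute_missing_covariates(state, return_moments=True)
        (mean, var), = moments.values()
        assert mean == 0.0 and var == 1.0

    def test_conditional_matches_hand_derived_update(self):
        """Single player, two stints: the conditional must equal the scalar
        normal-normal update assembled coefficient by coefficient."""
        state = self._state(with_obs=True)
        state.beta = np.array([0.3, 0.9])
        state.tau = 30.0
        state.eta = np.array([-0.55, -0.70])
        state._refresh_ability()
        moments = impute_missing_covariates(state, return_moments=True)
        (mean, var), = moments.values()
        # by hand: eta_j = alpha + gamma*(c + beta_x * x) + N(0, 1/tau)
        # => pseudo-obs on x: (eta_j - alpha - gamma*c)/(gamma*beta_x),
        #    variance 1/(tau * (gamma*beta_x)^2); prior N(0,1)
        g, bx, alpha, c = 0.5, 0.9, -0.8, 0.3 * 1.0
        obs_x = [(e - alpha - g * c) / (g * bx) for e in (-0.55, -0.70)]
        var_x = [1.0 / (30.0 * (g * bx) ** 2)] * 2
        o_mean, o_var = oracles.normal_normal_update(0.0, 1.0, obs_x, var_x)
        assert mean == pytest.approx(o_mean, rel=1e-10)
        assert var == pytest.approx(o_var, rel=1e-10)

    def test_imputed_draws_present_only_with_missingness(self):
        cal = make_calibration()
        ids = pd.Index(["P0"], name="player_id")
        X = pd.DataFrame({"x": [0.5]}, index=ids)
        obs = _toy_binomial_obs([40], [100], players=["P0"])
        spec = ModelSpec("OBP", cal, chains=1, iterations=20, burn_in=5, seed=0)
        chains = fit_binomial(obs, make_design(X), spec)
        assert chains.imputed is None
        chains2 = fit_binomial(obs, make_design(X, missing=[("P0", "x")]), spec)
        assert chains2.imputed is not None and chains2.imputed.shape[2] == 1


class TestChainSet:
    def _chains(self, tmp_path=None):
        cal = make_calibration(alpha_sd=0.05, gamma_sd=0.05)
        obs = _toy_binomial_obs([40, 60], [100, 120])
        X = pd.DataFrame({"intercept": [1.0, 1.0], "x": [0.3, -0.5]},
                         index=pd.Index(["P0", "P1"], name="player_id"))
        spec = ModelSpec("OBP", cal, chains=2, iterations=50, burn_in=10, seed=4)
        return fit_binomial(obs, make_design(X), spec)

    def test_shapes_and_positivity(self):
        chains = self._chains()
        assert chains.beta.shape == (2, 50, 2)
        assert (chains.tau > 0).all()
        assert np.isfinite(chains.eta).all()
        assert (chains.gamma > 0).all()

    def test_save_load_round_trip(self, tmp_path):
        chains = self._chains()
        path = tmp_path / "draws.csv"
        chains.save(path)
        back = ChainSet.load(path)
        np.testing.assert_allclose(back.beta, chains.beta)
        np.testing.assert_allclose(back.eta, chains.eta)
        assert back.coef_names == chains.coef_names
        assert back.statistic == "OBP"

    def test_seed_determinism(self):
        a = self._chains()
        b = self._chains()
        np.testing.assert_array_equal(a.beta, b.beta)


class TestPointwiseLoglik:
    def test_values_and_maximality(self):
        chains = TestChainSet()._chains()
        ll = pointwise_loglik(chains)
        assert ll.shape == (100, 2)
        assert np.isfinite(ll).all()
        # maximality at the empirical logit: perturbing eta lowers the log-pmf
        y, n = 40.0, 100.0
        eta_hat = np.log(y / (n - y))
        def lp(eta):
            from scipy.special import gammaln
            return (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
                    + y * eta - n * np.logaddexp(0, eta))
        assert lp(eta_hat) > lp(eta_hat + 0.3)
        assert lp(eta_hat) > lp(eta_hat - 0.3)

    def test_single_trial_coin_flip(self):
        # N=1, success, p=0.5 -> log 0.5 from the binomial formula directly
        from scipy.special import gammaln
        n, y, eta = 1.0, 1.0, 0.0
        val = (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
               + y * eta - n * np.logaddexp(0, eta))
        assert val == pytest.approx(np.log(0.5))

    def test_dimension_mismatch_rejected(self):
        chains = TestChainSet()._chains()
        with pytest.raises(ValueError, match="mismatch"):
            pointwise_loglik(chains, pd.DataFrame({"player_id": ["P0"]}))


@pytest.mark.parametrize("family", ["binomial", "normal"])
def test_joint_distribution_consistency(family):
    """Geweke-style check: marginal-conditional draws (prior + data sim) and
    successive-conditional draws (Gibbs sweep + data re-sim each step) must
    share moments for beta and the precision parameters."""
    rng = np.random.default_rng(99)
    ids = pd.Index([f"P{i}" for i in range(5)], name="player_id")
    X = pd.DataFrame({"intercept": 1.0, "x": rng.standard_normal(5)}, index=ids)
    stat = "OBP" if family == "binomial" else "SLG"
    cal = make_calibration(stat, leagues=("AAA", "MLB"), alpha=(-0.6, -0.9),
                           gamma=(0.4, 0.3), alpha_sd=0.05, gamma_sd=0.05)
    rows = []
    for i, pid in enumerate(ids):
        lg = "AAA" if i % 2 else "MLB"
        if family == "binomial":
            rows.append({"player_id": pid, "league": lg, "successes": 10, "trials": 40})
        else:
            rows.append({"player_id": pid, "league": lg, "value": 0.3, "weight": 40.0})
    obs = pd.DataFrame(rows)
    spec = ModelSpec(stat, cal, chains=1, iterations=10, burn_in=0,
                     prior_beta_var=1.0, prior_tau=(3.0, 3.0),
                     prior_sigma2=(4.0, 1.0), seed=0)
    design = make_design(X)

    M = 6000
    params = ["beta0", "beta1", "tau"] + (["sigma2"] if family == "normal" else [])

    def snapshot(state):
        out = [state.beta[0], state.beta[1], state.tau]
        if family == "normal":
            out.append(state.sigma2)
        return out

    marg_state = make_sampler(obs, design, spec, rng=np.random.default_rng(1))
    marginal = np.empty((M, len(params)))
    for t in range(M):
        marg_state.draw_from_priors()
        marginal[t] = snapshot(marg_state)

    succ_state = make_sampler(obs, design, spec, rng=np.random.default_rng(2))
    succ_state.draw_from_priors()
    succ_state.set_response(succ_state.simulate_response())
    successive = np.empty((M, len(params)))
    for t in range(M):
        succ_state.sweep()
        succ_state.set_response(succ_state.simulate_response())
        successive[t] = snapshot(succ_state)

    for j, name in enumerate(params):
        for g in (lambda v: v, lambda v: v**2):
            a, b = g(marginal[:, j]), g(successive[:, j])
            se = np.sqrt(a.var() / len(a) + oracles.batch_means_se(b) ** 2)
            z = (a.mean() - b.mean()) / se
            assert abs(z) < 4.0, f"{name}: z={z:.2f}"
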