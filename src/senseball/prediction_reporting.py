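"""Coefficient summaries, response-scale predictions, and the pipeline.

Worked-example predictions follow the logit-scale rule: an average player
(latent ability A = 0) in league j sits at the league baseline alpha_j; a
player shifted delta standard deviations on task t moves the linear
predictor by orientation * gamma_j * delta * beta_t, mapped back through
the inverse logit for rate statistics (identity for SLG/FIP).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .game_statistics import build_design_matrix
from .latent_ability_model import ChainSet, ModelSpec, fit_model, pointwise_loglik
from .league_calibration import LeagueCalibration, load_packaged_calibration
from .leagues import BATTER_STATISTICS, PITCHER_STATISTICS, orientation, response_family
from .model_selection_diagnostics import compare_models, compute_waic, comparison_table

__all__ = [
    "summarize_coefficients",
    "load_published_coefficients",
    "PredictionQuery",
    "predict_statistic",
    "obp_decomposition",
    "run_pipeline",
]

_PUBLISHED_COEF_FILE = "published_coefficients_v1.csv"


def summarize_coefficients(chains: ChainSet) -> pd.DataFrame:
    """Posterior mean, SD, 95% interval, zero-exclusion flag and z-score.

    The zero-exclusion flag marks coefficients whose 95% credible interval
    excludes zero (the bolding rule in report tables); the z-score
    (mean / SD) feeds the coefficient heat map.
    """
    draws = chains.coefficient_draws()
    if draws.empty:
        raise ValueError("chain set holds no draws")
    mean = draws.mean()
    sd = draws.std(ddof=1)
    q025 = draws.quantile(0.025)
    q975 = draws.quantile(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean / sd
    out = pd.DataFrame({
        "mean": mean, "sd": sd, "q2.5": q025, "q97.5": q975,
        "excludes_zero": (q025 > 0) | (q975 < 0),
        "z_score": z.replace([np.inf, -np.inf], np.nan).fillna(np.inf * np.sign(mean)),
    })
    out.index.name = "coefficient"
    return out


def load_published_coefficients(statistic: str) -> pd.DataFrame:
    """The published full-model coefficient summaries (OBP, BB%, K%)."""
    with resources.files("senseball.data").joinpath(_PUBLISHED_COEF_FILE).open() as fh:
        table = pd.read_csv(fh, comment="#")
    sub = table[table["statistic"] == statistic]
    if sub.empty:
        raise ValueError(
            f"no published coefficients for {statistic!r} "
            "(only the rate statistics were reported in full)"
        )
    out = sub.set_index("coefficient")[["mean", "sd", "q2.5", "q97.5"]].astype(float)
    out["excludes_zero"] = (out["q2.5"] > 0) | (out["q97.5"] < 0)
    out["z_score"] = out["mean"] / out["sd"]
    return out


@dataclass
class PredictionQuery:
    """A response-scale what-if: which statistic, league, and SD shifts.

    ``deltas`` maps coefficient names (e.g. ``perception_span``) to shifts
    in standard-deviation units of the training standardization.  The
    default baseline is the league-average player (A = 0); set
    ``include_intercept=True`` to add the intercept coefficient into the
    latent ability instead.
    """

    statistic: str
    league: str
    deltas: dict = field(default_factory=dict)
    baseline_mode: str = "average-player"
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("average-player", "explicit"):
            raise ValueError("baseline_mode must be 'average-player' or 'explicit'")


@dataclass
class PredictionResult:
    statistic: str
    league: str
    baseline: float
    predicted: float
    linear_predictor: float
    ability_shift: float

    def rounded(self) -> float:
        """Report-table rounding: 3 decimals for rates/averages."""
        return round(self.predicted, 3)


def predict_statistic(
    query: PredictionQuery,
    calibration: LeagueCalibration,
    coefficients: pd.DataFrame,
) -> PredictionResult:
    """Map a covariate shift through the fitted hierarchy to the response scale.

    linear predictor = alpha_j + orientation * gamma_j * sum_t delta_t * beta_t,
    inverse-logit for rate statistics, identity for SLG/FIP.
    """
    if calibration.statistic != query.statistic:
        raise ValueError(
            f"calibration is for {calibration.statistic!r}, query for {query.statistic!r}"
        )
    if query.league not in calibration.leagues:
        raise ValueError(f"league {query.league!r} not in calibration {calibration.leagues}")
    for name in query.deltas:
        if name == "go_no_go":
            raise ValueError("go_no_go is excluded from the models; no coefficient exists")
        if name not in coefficients.index:
            raise ValueError(f"no coefficient named {name!r}")
    s = orientation(query.statistic)
    alpha = float(calibration.alpha_mean[query.league])
    gamma = float(calibration.gamma_mean[query.league])
    shift = sum(float(coefficients.loc[t, "mean"]) * d for t, d in query.deltas.items())
    if query.include_intercept and "intercept" in coefficients.index:
        shift += float(coefficients.loc["intercept", "mean"])
    lp = alpha + s * gamma * shift
    fam = response_family(query.statistic)
    predicted = float(expit(lp)) if fam == "binomial" else lp
    baseline = float(expit(alpha)) if fam == "binomial" else alpha
    return PredictionResult(
        statistic=query.statistic, league=query.league, baseline=baseline,
        predicted=predicted, linear_predictor=lp, ability_shift=shift,
    )


def obp_decomposition(statistics: pd.DataFrame):
    """OLS of OBP on BB% and K% across players (the decomposition check).

    ``statistics`` needs columns ``OBP``, ``BB%``, ``K%`` (one row per
    player, or per stint).  Returns the fitted statsmodels results object;
    perfectly collinear predictors raise.
    """
    import statsmodels.api as sm

    required = {"OBP", "BB%", "K%"}
    if not required <= set(statistics.columns):
        raise ValueError(f"need columns {sorted(required)}")
    data = statistics[["OBP", "BB%", "K%"]].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 players with all three statistics")
    X = sm.add_constant(data[["BB%", "K%"]].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("BB% and K% are collinear; the decomposition is not estimable")
    model = sm.OLS(data["OBP"].to_numpy(), X)
    res = model.fit()
    res.coefficient_names = ["intercept", "BB%", "K%"]
    return res


# ---------------------------------------------------------------------------
# the end-to-end pipeline


_WORKED_EXAMPLES = (
    ("OBP", "MLB", {"perception_span": 1.0}),
    ("BB%", "MLB", {"eye_hand_coordination": 1.0}),
    ("K%", "MLB", {"perception_span": 1.0}),
)


def worked_example_predictions() -> pd.DataFrame:
    """The package's demonstration predictions from the published tables.

    For each example: the MLB baseline for an average player and the
    prediction after a +1 SD shift on one task, computed from the packaged
    calibration and published coefficients.
    """
    rows = []
    for stat, league, deltas in _WORKED_EXAMPLES:
        cal = load_packaged_calibration(stat)
        coefs = load_published_coefficients(stat)
        res = predict_statistic(PredictionQuery(stat, league, deltas), cal, coefs)
        rows.append({
            "statistic": stat, "league": league,
            "shifted_task": next(iter(deltas)), "delta_sd": deltas[next(iter(deltas))],
            "baseline": round(res.baseline, 3), "predicted": round(res.predicted, 3),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full analysis: simulate/ingest through report.

    ``config`` keys (all optional beyond ``seed``):

    - ``seed``: master seed for simulation and fitting.
    - ``statistics``: which responses to fit (default all five).
    - ``mcmc``: dict of chains / iterations / burn_in.
    - ``calibration``: 'packaged' (default) or 'fitted'.
    - ``synthetic``: overrides for the synthetic-population generator.

    Returns a bundle with the fitted chain sets, WAIC comparison table,
    coefficient summaries, worked-example predictions, and (when
    ``out_dir`` is given) a reproducibility manifest.
    """
    from . import __version__
    from .synthetic_data import (
        SyntheticConfig, apply_missingness, generate_outcomes, generate_population,
    )

    seed = int(config.get("seed", 0))
    stats = tuple(config.get("statistics", BATTER_STATISTICS + PITCHER_STATISTICS))
    mcmc = {"chains": 3, "iterations": 10_000, "burn_in": 1_000}
    mcmc.update(config.get("mcmc", {}))
    syn_overrides = dict(config.get("synthetic", {}))
    syn_overrides.setdefault("seed", seed)

    stage = "simulate"
    try:
        syn = SyntheticConfig(**syn_overrides)
        population = generate_population(syn)
        outcomes = generate_outcomes(population, syn)
        roles = population.players.set_index("player_id")["role"]
        battery = apply_missingness(population.battery, syn, roles=roles)

        stage = "design"
        designs = {}
        for role in ("batter", "pitcher"):
            ids = roles.index[roles == role]
            if len(ids) == 0:
                continue
            meta = population.players.set_index("player_id").loc[ids]
            designs[role] = build_design_matrix(
                battery.loc[ids], meta["age"],
                meta["position"] if role == "batter" else None, role=role,
            )

        results: dict = {"chains": {}, "waic": {}, "summaries": {}}
        for stat in stats:
            stage = f"fit:{stat}"
            role = "batter" if stat in BATTER_STATISTICS else "pitcher"
            if role not in designs:
                continue
            cal = load_packaged_calibration(stat)
            obs = outcomes[outcomes["statistic"] == stat]
            fitted = {}
            for cov_set in ("full", "reduced"):
                spec = ModelSpec(
                    statistic=stat, calibration=cal, covariate_set=cov_set,
                    seed=seed, **mcmc,
                )
                fitted[cov_set] = fit_model(obs, designs[role], spec)
            results["chains"][stat] = fitted
            results["waic"][stat] = (
                compute_waic(pointwise_loglik(fitted["full"])),
                compute_waic(pointwise_loglik(fitted["reduced"])),
            )
            results["summaries"][stat] = summarize_coefficients(fitted["full"])

        stage = "compare"
        results["comparison_table"] = comparison_table(results["waic"])
        results["verdicts"] = {
            stat: compare_models(full, reduced)
            for stat, (full, reduced) in results["waic"].items()
        }

        stage = "predict"
        results["worked_examples"] = worked_example_predictions()

        if out_dir is not None:
            stage = "write"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            results["comparison_table"].to_csv(out / "waic_comparison.csv")
            for stat, summary in results["summaries"].items():
                safe = stat.replace("%", "pct")
                summary.to_csv(out / f"coefficients_{safe}.csv")
            results["worked_examples"].to_csv(out / "worked_examples.csv", index=False)
            for stat, fitted in results["chains"].items():
                safe = stat.replace("%", "pct")
                fitted["full"].save(out / f"chains_{safe}_full.csv")
            manifest = {
                "seed": seed,
                "statistics": list(stats),
                "mcmc": mcmc,
                "config_hash": hashlib.sha256(
                    json.dumps(config, sort_keys=True, default=str).encode()
                ).hexdigest(),
                "package_version": __version__,
            }
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
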