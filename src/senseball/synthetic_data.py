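"""Seeded synthetic player populations with the model's exact generative law.

The study population this emulates is a cohort of professional baseball
players (141 batters, 111 pitchers after the playing-time filter) assessed
on a nine-task sensorimotor battery, with per-league game statistics in the
following season.  The generator reproduces that structure end to end:

* ages and positions drawn to match the cohort's published moments,
* correlated task scores with a right-skewed (log-normal) depth-perception
  task so the log transform is meaningful,
* league assignments spanning the six-league ladder, with a configurable
  share of players appearing in two adjacent leagues (these multi-league
  stints are what identifies the stage-1 calibration),
* stint outcomes drawn from the binomial-logit / weighted-normal hierarchy
  itself, so parameter-recovery tests have exact ground truth,
* missing-completely-at-random holes in depth perception.

Default parameter values are the study conditions: league difficulty and
ability-impact defaults come from the packaged stage-1 calibration, and the
default coefficient vectors for OBP/BB%/K% are the published posterior
means.  SLG and FIP default to null sensorimotor effects (the study found
none) with a survivorship-driven age effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .game_statistics import (
    BATTER_COEFFICIENTS,
    PITCHER_COEFFICIENTS,
    TASK_COLUMNS,
    DesignMatrix,
    build_design_matrix,
)
from .leagues import (
    BATTER_STATISTICS,
    LEAGUES,
    PITCHER_STATISTICS,
    orientation,
    response_family,
)
from .league_calibration import load_packaged_calibration

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "Population",
    "generate_population",
    "generate_outcomes",
    "apply_missingness",
    "population_to_count_lines",
    "write_population_csvs",
]


def _default_league_params() -> dict:
    """(alpha, gamma) per statistic per league, from the packaged calibration."""
    out = {}
    for stat in BATTER_STATISTICS + PITCHER_STATISTICS:
        cal = load_packaged_calibration(stat)
        out[stat] = {
            "alpha": cal.alpha_mean.to_numpy(dtype=float),
            "gamma": cal.gamma_mean.to_numpy(dtype=float),
        }
    return out


#: Published full-model posterior means used as default coefficient truth,
#: in canonical coefficient order (intercept, eight tasks, age, dummies).
_PUBLISHED_BETA = {
    "OBP": [-0.13, -0.24, 0.13, 0.19, -0.02, 0.15, 0.64, 0.22, 0.21, 0.66, -0.53, -1.28],
    "BB%": [-0.84, -0.15, 0.04, 0.21, -0.05, -0.16, 0.15, 0.46, 0.23, 0.53, 0.05, 0.15],
    "K%": [-0.52, -0.08, 0.14, -0.12, 0.21, 0.16, 0.34, -0.19, 0.12, 0.22, 0.65, 0.26],
}


def _default_beta() -> dict:
    beta = {k: np.asarray(v, dtype=float) for k, v in _PUBLISHED_BETA.items()}
    # no sensorimotor signal for the power/pitching statistics; age effect
    # reflects survivorship (older professionals are selectively better)
    slg = np.zeros(len(BATTER_COEFFICIENTS))
    slg[BATTER_COEFFICIENTS.index("age")] = 0.3
    beta["SLG"] = slg
    fip = np.zeros(len(PITCHER_COEFFICIENTS))
    fip[PITCHER_COEFFICIENTS.index("age")] = 0.3
    beta["FIP"] = fip
    return beta


def _default_tau() -> dict:
    # overdispersion precision of the latent layer, per statistic: logit-scale
    # SD 0.2 for the rates; response-scale SD ~0.04 (SLG) and ~0.9 (FIP)
    return {"OBP": 25.0, "BB%": 25.0, "K%": 25.0, "SLG": 700.0, "FIP": 1.2}


def _default_sigma2() -> dict:
    # per-opportunity sampling variance of the normal responses
    return {"SLG": 0.6, "FIP": 60.0}


def _default_correlation() -> np.ndarray:
    """Latent correlation among the nine task scores.

    The study does not publish the task covariance; a modest common
    correlation is used, with go/no-go tied strongly to eye-hand
    coordination (their collinearity is why go/no-go is excluded from the
    models).
    """
    k = len(TASK_COLUMNS)
    r = np.full((k, k), 0.2)
    np.fill_diagonal(r, 1.0)
    i = TASK_COLUMNS.index("go_no_go")
    j = TASK_COLUMNS.index("eye_hand_coordination")
    r[i, j] = r[j, i] = 0.7
    return r


#: Location/scale of each task in its native units.  Units are arbitrary
#: for the models (everything is standardized); depth perception is
#: generated log-normal (right-skewed, strictly positive).
_TASK_SCALES = {
    "visual_clarity": (0.0, 1.0),
    "contrast_sensitivity": (1.8, 0.3),
    "depth_perception": (np.log(30.0), 0.6),  # meanlog, sdlog
    "near_far_quickness": (28.0, 5.0),
    "target_capture": (250.0, 40.0),
    "perception_span": (45.0, 10.0),
    "eye_hand_coordination": (380.0, 40.0),
    "go_no_go": (20.0, 8.0),
    "reaction_time": (350.0, 35.0),
}

#: League membership frequencies observed in the cohort (stints per league).
_LEAGUE_WEIGHTS = {
    "batter": np.array([63, 18, 33, 17, 23, 14], dtype=float),
    "pitcher": np.array([29, 17, 24, 21, 17, 13], dtype=float),
}


@dataclass
class SyntheticConfig:
    """Generative truth and population settings.

    Defaults are the study conditions: cohort sizes and demographics from
    the published sample characteristics, league parameters from the
    packaged calibration, rate-statistic coefficients from the published
    full-model posterior means, and about four missing depth-perception
    measurements per role.
    """

    n_batters: int = 141
    n_pitchers: int = 111
    seed: int = 0
    league_set: tuple = LEAGUES
    alpha_true: dict = field(default_factory=dict)
    gamma_true: dict = field(default_factory=dict)
    beta_true: dict = field(default_factory=_default_beta)
    tau_true: dict = field(default_factory=_default_tau)
    sigma2_true: dict = field(default_factory=_default_sigma2)
    covariate_correlation: np.ndarray = field(default_factory=_default_correlation)
    missing_rate_batters: float = 4.0 / 141.0
    missing_rate_pitchers: float = 4.0 / 111.0
    multi_league_rate: float = 0.30
    pa_range: tuple = (50, 600)       # plate appearances per batting stint
    innings_range: tuple = (31, 180)  # innings pitched per pitching stint
    age_moments: dict = field(default_factory=lambda: {
        "batter": (22.7, 3.9, 17.0, 37.0), "pitcher": (23.7, 3.6, 18.0, 39.0)})
    position_counts: tuple = (19, 65, 57)  # catcher, infielder, outfielder

    def __post_init__(self) -> None:
        if self.n_batters < 0 or self.n_pitchers < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not (0.0 <= self.missing_rate_batters < 1.0
                and 0.0 <= self.missing_rate_pitchers < 1.0):
            raise ValueError("missing rates must lie in [0, 1)")
        if not 0.0 <= self.multi_league_rate <= 1.0:
            raise ValueError("multi_league_rate must lie in [0, 1]")
        packaged = _default_league_params()
        # partial overrides merge over the study-condition defaults
        self.alpha_true = {
            **{s: p["alpha"].copy() for s, p in packaged.items()}, **self.alpha_true
        }
        self.gamma_true = {
            **{s: p["gamma"].copy() for s, p in packaged.items()}, **self.gamma_true
        }
        self.beta_true = {**_default_beta(), **self.beta_true}
        self.tau_true = {**_default_tau(), **self.tau_true}
        self.sigma2_true = {**_default_sigma2(), **self.sigma2_true}
        for stat, g in self.gamma_true.items():
            if np.any(np.asarray(g) <= 0):
                raise ValueError(f"gamma_true must be positive elementwise ({stat})")
        self.covariate_correlation = np.asarray(self.covariate_correlation, dtype=float)
        eigvals = np.linalg.eigvalsh(self.covariate_correlation)
        if eigvals.min() <= 0:
            raise ValueError("covariate_correlation must be positive definite")
        for stat, tau in self.tau_true.items():
            if tau <= 0:
                raise ValueError(f"tau_true must be positive ({stat})")
        for stat, s2 in self.sigma2_true.items():
            if s2 <= 0:
                raise ValueError(f"sigma2_true must be positive ({stat})")

    def echo(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, dict):
                v = {k: (x.tolist() if isinstance(x, np.ndarray) else x) for k, x in v.items()}
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out


@dataclass
class TruthRecord:
    """Ground truth behind a synthetic population.

    ``ability`` has one row per player and one column per statistic of the
    player's role: A_i = x_i' beta_true computed from the pre-missingness
    standardized covariates.  ``linear_predictors`` is filled in by
    ``generate_outcomes`` with the per-stint latent draws.
    """

    ability: pd.DataFrame
    design: dict                      # role -> DesignMatrix (pre-missingness)
    config: dict
    linear_predictors: pd.DataFrame | None = None


@dataclass
class Population:
    players: pd.DataFrame   # player_id, role, age, position
    battery: pd.DataFrame   # player_id x nine task scores (no holes)
    stints: pd.DataFrame    # player_id, league, role, plate_appearances/at_bats/innings
    truth: TruthRecord


def _draw_ages(rng, n, mean, sd, lo, hi):
    ages = rng.normal(mean, sd, size=n)
    return np.clip(ages, lo, hi)


def _draw_battery(rng, n, config) -> pd.DataFrame:
    z = rng.multivariate_normal(
        np.zeros(len(TASK_COLUMNS)), config.covariate_correlation, size=n,
        method="cholesky",
    )
    cols = {}
    for j, task in enumerate(TASK_COLUMNS):
        loc, scale = _TASK_SCALES[task]
        if task == "depth_perception":
            cols[task] = np.exp(loc + scale * z[:, j])
        else:
            cols[task] = loc + scale * z[:, j]
    return pd.DataFrame(cols)


def _assign_leagues(rng, n, role, config):
    """Primary league from the cohort frequencies; a share of players adds
    one adjacent-league stint (the bridge stage 1 needs)."""
    w = _LEAGUE_WEIGHTS[role]
    w = w / w.sum()
    primary = rng.choice(len(LEAGUES), size=n, p=w)
    two = rng.random(n) < config.multi_league_rate
    assignments = []
    for i in range(n):
        lgs = [int(primary[i])]
        if two[i]:
            j = lgs[0]
            if j == 0:
                other = 1
            elif j == len(LEAGUES) - 1:
                other = j - 1
            else:
                other = j + (1 if rng.random() < 0.5 else -1)
            lgs.append(other)
        assignments.append(sorted(lgs))
    return assignments


def generate_population(config: SyntheticConfig | None = None) -> Population:
    """Draw a seeded synthetic cohort: players, batteries, stints, truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(0,)))
    frames, batteries, stints = [], [], []
    designs: dict[str, DesignMatrix] = {}
    abilities = []
    for role, n in (("batter", config.n_batters), ("pitcher", config.n_pitchers)):
        if n == 0:
            continue
        mean, sd, lo, hi = config.age_moments[role]
        prefix = "B" if role == "batter" else "P"
        ids = pd.Index([f"{prefix}{i:04d}" for i in range(n)], name="player_id")
        ages = pd.Series(_draw_ages(rng, n, mean, sd, lo, hi), index=ids)
        if role == "batter":
            pc = np.asarray(config.position_counts, dtype=float)
            positions = pd.Series(
                rng.choice(["catcher", "infielder", "outfielder"], size=n, p=pc / pc.sum()),
                index=ids,
            )
        else:
            positions = pd.Series("pitcher", index=ids)
        battery = _draw_battery(rng, n, config)
        battery.index = ids
        frames.append(pd.DataFrame({
            "player_id": ids, "role": role, "age": ages.values,
            "position": positions.values,
        }))
        batteries.append(battery.reset_index())

        design = build_design_matrix(
            battery, ages, positions if role == "batter" else None, role=role,
        )
        designs[role] = design
        stats = BATTER_STATISTICS if role == "batter" else PITCHER_STATISTICS
        ab = {}
        for stat in stats:
            beta = np.asarray(config.beta_true[stat], dtype=float)
            if len(beta) != design.X.shape[1]:
                raise ValueError(
                    f"beta_true[{stat!r}] has length {len(beta)}, design has "
                    f"{design.X.shape[1]} columns"
                )
            ab[stat] = design.X.to_numpy() @ beta
        ability = pd.DataFrame(ab, index=ids)
        ability.insert(0, "role", role)
        abilities.append(ability)

        assignments = _assign_leagues(rng, n, role, config)
        for pid, lgs in zip(ids, assignments):
            for lg in lgs:
                row = {"player_id": pid, "role": role, "league": LEAGUES[lg]}
                if role == "batter":
                    pa = int(rng.integers(config.pa_range[0], config.pa_range[1] + 1))
                    row["plate_appearances"] = pa
                    # at-bats are plate appearances minus walks and the odd
                    # HBP/SF; keep them comfortably above the >30 filter
                    row["at_bats"] = max(int(round(pa * 0.88)), 31)
                else:
                    thirds = int(rng.integers(config.innings_range[0] * 3,
                                              config.innings_range[1] * 3 + 1))
                    row["innings_pitched"] = thirds / 3.0
                stints.append(row)

    players = pd.concat(frames, ignore_index=True)
    battery = pd.concat(batteries, ignore_index=True).set_index("player_id")
    stints = pd.DataFrame(stints)
    truth = TruthRecord(
        ability=pd.concat(abilities),
        design=designs,
        config=config.echo(),
    )
    return Population(players=players, battery=battery, stints=stints, truth=truth)


def generate_outcomes(
    population: Population,
    config: SyntheticConfig,
    statistics: tuple | None = None,
) -> pd.DataFrame:
    """Draw per-stint outcomes from the hierarchy's exact generative law.

    Returns a tidy frame (player_id, league, statistic, and either
    successes/trials or value/weight) plus the latent truth columns
    ``linear_predictor`` (alpha_j ± gamma_j A_i), ``eta`` (the realized
    logit(p_ij) or mu_ij) and ``p`` / ``mu``.  The truth columns are also
    recorded on ``population.truth.linear_predictors``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(1,)))
    if statistics is None:
        statistics = BATTER_STATISTICS + PITCHER_STATISTICS
    rows = []
    ability = population.truth.ability
    for stat in statistics:
        role = "batter" if stat in BATTER_STATISTICS else "pitcher"
        fam = response_family(stat)
        s = orientation(stat)
        alpha = np.asarray(config.alpha_true[stat], dtype=float)
        gamma = np.asarray(config.gamma_true[stat], dtype=float)
        tau = float(config.tau_true[stat])
        stints = population.stints[population.stints["role"] == role]
        if stints.empty:
            continue
        li = stints["league"].map(LEAGUES.index).to_numpy()
        a_i = ability.loc[stints["player_id"], stat].to_numpy()
        m = alpha[li] + s * gamma[li] * a_i
        eta = rng.normal(m, 1.0 / np.sqrt(tau))
        if fam == "binomial":
            trials = stints["plate_appearances"].to_numpy(dtype=np.int64)
            p = expit(eta)
            successes = rng.binomial(trials, p)
            rows.append(pd.DataFrame({
                "player_id": stints["player_id"].to_numpy(),
                "league": stints["league"].to_numpy(), "statistic": stat,
                "successes": successes, "trials": trials,
                "value": successes / trials, "weight": np.nan,
                "linear_predictor": m, "eta": eta, "p": p, "mu": np.nan,
            }))
        else:
            weight_col = "at_bats" if stat == "SLG" else "innings_pitched"
            weight = stints[weight_col].to_numpy(dtype=float)
            sigma2 = float(config.sigma2_true[stat])
            value = rng.normal(eta, np.sqrt(sigma2 / weight))
            rows.append(pd.DataFrame({
                "player_id": stints["player_id"].to_numpy(),
                "league": stints["league"].to_numpy(), "statistic": stat,
                "successes": np.nan, "trials": np.nan,
                "value": value, "weight": weight,
                "linear_predictor": m, "eta": eta, "p": np.nan, "mu": eta,
            }))
    out = pd.concat(rows, ignore_index=True)
    population.truth.linear_predictors = out[
        ["player_id", "league", "statistic", "linear_predictor", "eta"]
    ].copy()
    return out


def apply_missingness(battery: pd.DataFrame, config: SyntheticConfig,
                      roles: pd.Series | None = None) -> pd.DataFrame:
    """Punch missing-completely-at-random holes in depth perception.

    The number of holes per role is the rounded expected count (the study
    had exactly four per role), their positions uniformly random.
    """
    out = battery.copy()
    if roles is None:
        roles = pd.Series(
            np.where(out.index.str.startswith("B"), "batter", "pitcher"), index=out.index
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(2,)))
    for role, rate in (("batter", config.missing_rate_batters),
                       ("pitcher", config.missing_rate_pitchers)):
        ids = out.index[roles == role]
        k = int(round(rate * len(ids)))
        if k == 0:
            continue
        holes = rng.choice(len(ids), size=k, replace=False)
        out.loc[ids[holes], "depth_perception"] = np.nan
    return out


# ---------------------------------------------------------------------------
# count-line composition (the CSV surface the statistics module reads)


def population_to_count_lines(population: Population, outcomes: pd.DataFrame,
                              config: SyntheticConfig) -> dict:
    """Compose raw counting lines consistent with the drawn statistics.

    The five statistics are modeled independently, so the counting lines
    reconcile them with light clipping (hits within at-bats, total bases at
    least hits).  Exact-law observations for model fitting come straight
    from ``generate_outcomes``; these lines exercise the ingest path.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(3,)))
    by_key = {
        (r["player_id"], r["league"], r["statistic"]): r
        for _, r in outcomes.iterrows()
    }
    batting_rows, pitching_rows = [], []
    for _, st in population.stints.iterrows():
        pid, lg = st["player_id"], st["league"]
        if st["role"] == "batter":
            pa = int(st["plate_appearances"])
            bb = int(by_key[(pid, lg, "BB%")]["successes"])
            k = int(by_key[(pid, lg, "K%")]["successes"])
            hbp = int(rng.binomial(pa, 0.009))
            sf = int(rng.binomial(pa, 0.007))
            ab = max(pa - bb - hbp - sf, 31)
            bb = pa - ab - hbp - sf  # re-balance so the identity holds
            ob = int(by_key[(pid, lg, "OBP")]["successes"])
            hits = int(np.clip(ob - bb - hbp, 0, ab))
            k = min(k, ab)
            slg_val = float(by_key[(pid, lg, "SLG")]["value"])
            tb = int(np.clip(round(slg_val * ab), hits, 4 * ab))
            batting_rows.append(dict(
                player_id=pid, league=lg, hits=hits, walks=bb, hit_by_pitch=hbp,
                at_bats=ab, sacrifice_flies=sf, plate_appearances=pa,
                strikeouts=k, total_bases=tb,
            ))
        else:
            ip = float(st["innings_pitched"])
            fip_val = float(by_key[(pid, lg, "FIP")]["value"])
            hr = int(rng.poisson(0.10 * ip))
            bb = int(rng.poisson(0.35 * ip))
            hbp = int(rng.poisson(0.03 * ip))
            # solve the strikeout count so the line reproduces the drawn FIP,
            # rebalancing HR/BB when the required count leaves [0, 3*IP]
            from .game_statistics import DEFAULT_FIP_CONSTANT
            target = (fip_val - DEFAULT_FIP_CONSTANT) * ip
            k = 0.0
            for _ in range(4):
                k = (13 * hr + 3 * (bb + hbp) - target) / 2.0
                if k < 0:
                    hr += int(np.ceil(-k * 2.0 / 13.0))
                elif k > 3 * ip:
                    bb += int(np.ceil((k - 3 * ip) * 2.0 / 3.0))
                else:
                    break
            k = int(np.clip(round(k), 0, round(ip * 3)))
            pitching_rows.append(dict(
                player_id=pid, league=lg, home_runs=hr, walks=bb,
                hit_by_pitch=hbp, strikeouts=k, innings_pitched=ip,
            ))
    return {
        "batting": pd.DataFrame(batting_rows),
        "pitching": pd.DataFrame(pitching_rows),
    }


def write_population_csvs(population: Population, outcomes: pd.DataFrame,
                          config: SyntheticConfig, out_dir) -> dict:
    """Write the CSV bundle (players, battery incl. holes, lines, truth, config)."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    holed = apply_missingness(population.battery, config,
                              roles=population.players.set_index("player_id")["role"])
    lines = population_to_count_lines(population, outcomes, config)
    paths = {}
    for name, frame in (
        ("players", population.players),
        ("battery", holed.reset_index()),
        ("batting_lines", lines["batting"]),
        ("pitching_lines", lines["pitching"]),
        ("outcomes", outcomes),
        ("truth_ability", population.truth.ability.reset_index()),
    ):
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config.echo(), fh, sort_keys=False)
    paths["config"] = cfg_path
    return paths
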