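"""Response-statistic definitions, eligibility filtering, and the design matrix.

Five statistics summarize on-field production.  For batters: on-base
percentage (OBP), walk rate (BB%), strikeout rate (K%) and slugging
percentage (SLG); for pitchers: fielder-independent pitching (FIP).  The
rate statistics are success counts over opportunity counts and feed a
binomial response model; SLG and FIP are long-run per-opportunity averages
and feed a weighted-normal response model, with the opportunity count as the
weight.

The design matrix holds the player-level covariates that define latent
ability: eight standardized sensorimotor task scores (depth perception on
the log scale; go/no-go excluded), standardized age, and — for batters —
catcher/infielder indicators with outfielder as the reference category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .leagues import LEAGUES

__all__ = [
    "DegenerateInputError",
    "BattingLine",
    "PitchingLine",
    "BinomialOutcome",
    "WeightedOutcome",
    "DesignMatrix",
    "compute_obp",
    "compute_bb_rate",
    "compute_k_rate",
    "compute_slg",
    "compute_fip",
    "eligibility_filter",
    "build_design_matrix",
    "batting_statistics_table",
    "pitching_statistics_table",
    "TASK_COLUMNS",
    "MODEL_TASKS",
    "BATTER_COEFFICIENTS",
    "PITCHER_COEFFICIENTS",
    "REDUCED_BATTER_COEFFICIENTS",
    "REDUCED_PITCHER_COEFFICIENTS",
    "DEFAULT_FIP_CONSTANT",
]


class DegenerateInputError(ValueError):
    """Raised when a statistic's denominator is zero or a column is unusable."""


#: The nine tasks of the sensorimotor battery, in canonical order.
TASK_COLUMNS = (
    "visual_clarity",
    "contrast_sensitivity",
    "depth_perception",
    "near_far_quickness",
    "target_capture",
    "perception_span",
    "eye_hand_coordination",
    "go_no_go",
    "reaction_time",
)

#: Tasks entering the models.  Go/no-go is excluded (highly collinear with
#: eye-hand coordination); depth perception enters on the log scale.
MODEL_TASKS = tuple(t for t in TASK_COLUMNS if t != "go_no_go")

_TASK_DESIGN_NAMES = tuple(
    "log_depth_perception" if t == "depth_perception" else t for t in MODEL_TASKS
)

BATTER_COEFFICIENTS = ("intercept",) + _TASK_DESIGN_NAMES + ("age", "is_infielder", "is_catcher")
PITCHER_COEFFICIENTS = ("intercept",) + _TASK_DESIGN_NAMES + ("age",)
REDUCED_BATTER_COEFFICIENTS = ("intercept", "age", "is_infielder", "is_catcher")
REDUCED_PITCHER_COEFFICIENTS = ("intercept", "age")

POSITIONS = ("catcher", "infielder", "outfielder")

#: The FIP formula adds a league-calibration constant placing the result on
#: the ERA scale; 3.10 is a conventional choice and it is configurable.
DEFAULT_FIP_CONSTANT = 3.10


def _check_count(name: str, value) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class BattingLine:
    """One batter's aggregated counting line within one league (a stint)."""

    player_id: str
    league: str
    hits: int
    walks: int
    hit_by_pitch: int
    at_bats: int
    sacrifice_flies: int
    plate_appearances: int
    strikeouts: int
    total_bases: int

    def __post_init__(self) -> None:
        if self.league not in LEAGUES:
            raise ValueError(f"unknown league {self.league!r}; expected one of {LEAGUES}")
        for f in (
            "hits", "walks", "hit_by_pitch", "at_bats",
            "sacrifice_flies", "plate_appearances", "strikeouts", "total_bases",
        ):
            _check_count(f, getattr(self, f))
        if self.hits > self.at_bats:
            raise ValueError("hits cannot exceed at_bats")
        if self.total_bases < self.hits:
            raise ValueError("total_bases cannot be below hits")
        if self.strikeouts > self.at_bats:
            raise ValueError("strikeouts cannot exceed at_bats")
        if self.plate_appearances < self.walks + self.strikeouts:
            raise ValueError("plate_appearances must cover walks + strikeouts")


@dataclass(frozen=True)
class PitchingLine:
    """One pitcher's aggregated counting line within one league (a stint).

    ``innings_pitched`` is a real number of innings: 31.2 "baseball" innings
    (31 innings and two outs) must be recorded as 31 + 2/3.
    """

    player_id: str
    league: str
    home_runs: int
    walks: int
    hit_by_pitch: int
    strikeouts: int
    innings_pitched: float

    def __post_init__(self) -> None:
        if self.league not in LEAGUES:
            raise ValueError(f"unknown league {self.league!r}; expected one of {LEAGUES}")
        for f in ("home_runs", "walks", "hit_by_pitch", "strikeouts"):
            _check_count(f, getattr(self, f))
        if self.innings_pitched < 0:
            raise ValueError("innings_pitched must be >= 0")


class BinomialOutcome(NamedTuple):
    """A proportion together with the integer (successes, trials) pair behind it."""

    value: float
    successes: int
    trials: int


class WeightedOutcome(NamedTuple):
    """A per-opportunity average together with its opportunity-count weight."""

    value: float
    weight: float


def compute_obp(line: BattingLine) -> BinomialOutcome:
    """On-base percentage: (H + BB + HBP) / (AB + BB + HBP + SF)."""
    trials = line.at_bats + line.walks + line.hit_by_pitch + line.sacrifice_flies
    if trials <= 0:
        raise DegenerateInputError(
            f"OBP denominator is zero for player {line.player_id!r} in {line.league}"
        )
    successes = line.hits + line.walks + line.hit_by_pitch
    return BinomialOutcome(successes / trials, successes, trials)


def compute_bb_rate(line: BattingLine) -> BinomialOutcome:
    """Walk rate: walks per plate appearance."""
    if line.plate_appearances <= 0:
        raise DegenerateInputError(
            f"zero plate appearances for player {line.player_id!r} in {line.league}"
        )
    return BinomialOutcome(
        line.walks / line.plate_appearances, line.walks, line.plate_appearances
    )


def compute_k_rate(line: BattingLine) -> BinomialOutcome:
    """Strikeout rate: strikeouts per plate appearance."""
    if line.plate_appearances <= 0:
        raise DegenerateInputError(
            f"zero plate appearances for player {line.player_id!r} in {line.league}"
        )
    return BinomialOutcome(
        line.strikeouts / line.plate_appearances, line.strikeouts, line.plate_appearances
    )


def compute_slg(line: BattingLine) -> WeightedOutcome:
    """Slugging percentage: total bases per at-bat, weighted by at-bats."""
    if line.at_bats <= 0:
        raise DegenerateInputError(
            f"zero at-bats for player {line.player_id!r} in {line.league}"
        )
    return WeightedOutcome(line.total_bases / line.at_bats, float(line.at_bats))


def compute_fip(line: PitchingLine, fip_constant: float = DEFAULT_FIP_CONSTANT) -> WeightedOutcome:
    """Fielder-independent pitching: (13*HR + 3*(BB+HBP) - 2*K) / IP + constant.

    The formula has no floor; a strikeout-heavy line can produce a negative
    FIP and that is returned as-is.
    """
    if line.innings_pitched <= 0:
        raise DegenerateInputError(
            f"zero innings pitched for player {line.player_id!r} in {line.league}"
        )
    core = (
        13.0 * line.home_runs
        + 3.0 * (line.walks + line.hit_by_pitch)
        - 2.0 * line.strikeouts
    ) / line.innings_pitched
    return WeightedOutcome(core + fip_constant, float(line.innings_pitched))


# ---------------------------------------------------------------------------
# eligibility filter


def eligibility_filter(lines, role: str):
    """Retain the (player, league) stints with enough playing time to model.

    Batters need *more than* 30 at-bats in the stint; pitchers *more than*
    30 innings pitched (both strict).  Accepts either a DataFrame with an
    ``at_bats`` / ``innings_pitched`` column or an iterable of line objects;
    returns the same kind.  A player survives if any of their stints does.
    """
    if role not in ("batter", "pitcher"):
        raise ValueError(f"role must be 'batter' or 'pitcher', got {role!r}")
    column = "at_bats" if role == "batter" else "innings_pitched"
    if isinstance(lines, pd.DataFrame):
        return lines.loc[lines[column] > 30].copy()
    return [ln for ln in lines if getattr(ln, column) > 30]


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Standardized covariates for one role's analyzed player pool.

    ``X`` has one row per player and the coefficient columns in canonical
    order.  Missing entries (absent depth-perception measurements) are
    flagged in ``missing_mask`` and hold 0.0 placeholders in ``X``; the
    Gibbs sampler imputes them.  ``standardization`` records the mean/SD
    used per column so prediction-time profiles can reuse the training
    scaling.
    """

    X: pd.DataFrame
    missing_mask: pd.DataFrame
    standardization: pd.DataFrame  # index: column; columns: mean, sd
    role: str

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    @property
    def player_ids(self) -> pd.Index:
        return self.X.index

    def reduced(self) -> "DesignMatrix":
        """The control-only design (intercept, age, position dummies)."""
        cols = list(
            REDUCED_BATTER_COEFFICIENTS if self.role == "batter" else REDUCED_PITCHER_COEFFICIENTS
        )
        return DesignMatrix(
            X=self.X[cols].copy(),
            missing_mask=self.missing_mask[cols].copy(),
            standardization=self.standardization.loc[
                [c for c in cols if c in self.standardization.index]
            ].copy(),
            role=self.role,
        )


def _standardize(series: pd.Series, name: str) -> tuple[pd.Series, float, float]:
    present = series.dropna()
    if len(present) < 2:
        raise DegenerateInputError(f"column {name!r} has fewer than 2 non-missing values")
    mean = float(present.mean())
    sd = float(present.std(ddof=1))
    if sd == 0.0 or not math.isfinite(sd):
        raise DegenerateInputError(f"column {name!r} has zero variance; cannot standardize")
    return (series - mean) / sd, mean, sd


def build_design_matrix(
    batteries: pd.DataFrame,
    ages: pd.Series,
    positions: pd.Series | None = None,
    role: str = "batter",
) -> DesignMatrix:
    """Assemble the standardized covariate matrix for one role's player pool.

    Parameters
    ----------
    batteries
        One row per player (index = player id), columns the nine task
        scores.  ``depth_perception`` may contain NaN (missing); all its
        present values must be positive since it is log-transformed before
        standardization.  ``go_no_go`` is dropped.
    ages
        Age in years, aligned to ``batteries``.
    positions
        For batters: 'catcher' / 'infielder' / 'outfielder' per player.
        Ignored for pitchers (pitcher designs carry no position dummies).
    role
        'batter' or 'pitcher'.
    """
    if role not in ("batter", "pitcher"):
        raise ValueError(f"role must be 'batter' or 'pitcher', got {role!r}")
    missing_tasks = [t for t in TASK_COLUMNS if t not in batteries.columns]
    if missing_tasks:
        raise ValueError(f"battery table lacks task columns: {missing_tasks}")
    ages = ages.reindex(batteries.index)
    if ages.isna().any():
        raise ValueError("every player needs an age")

    cols: dict[str, pd.Series] = {}
    stats_rows: dict[str, tuple[float, float]] = {}
    index = batteries.index

    cols["intercept"] = pd.Series(1.0, index=index)

    for task, design_name in zip(MODEL_TASKS, _TASK_DESIGN_NAMES):
        raw = batteries[task].astype(float)
        if task == "depth_perception":
            if (raw.dropna() <= 0).any():
                raise DegenerateInputError(
                    "depth_perception must be positive to take logs"
                )
            raw = np.log(raw)
        z, mean, sd = _standardize(raw, design_name)
        cols[design_name] = z
        stats_rows[design_name] = (mean, sd)

    z_age, a_mean, a_sd = _standardize(ages.astype(float), "age")
    cols["age"] = z_age
    stats_rows["age"] = (a_mean, a_sd)

    if role == "batter":
        if positions is None:
            raise ValueError("batter design matrices need positions")
        positions = positions.reindex(index)
        bad = set(positions.dropna().unique()) - set(POSITIONS)
        if bad:
            raise ValueError(f"unknown positions {sorted(bad)}; expected {POSITIONS}")
        if positions.isna().any():
            raise ValueError("every batter needs a position")
        cols["is_infielder"] = (positions == "infielder").astype(float)
        cols["is_catcher"] = (positions == "catcher").astype(float)
        order = list(BATTER_COEFFICIENTS)
    else:
        order = list(PITCHER_COEFFICIENTS)

    X = pd.DataFrame(cols)[order]
    missing_mask = X.isna()
    X = X.fillna(0.0)
    standardization = pd.DataFrame(
        stats_rows, index=["mean", "sd"]
    ).T.loc[[c for c in order if c in stats_rows]]
    return DesignMatrix(X=X, missing_mask=missing_mask, standardization=standardization, role=role)


# ---------------------------------------------------------------------------
# tidy statistic tables


def batting_statistics_table(
    lines: Iterable[BattingLine] | pd.DataFrame,
) -> pd.DataFrame:
    """Tidy per-stint statistics: one row per (player, league, statistic).

    Binomial statistics carry (successes, trials); SLG carries
    (value, weight).
    """
    if isinstance(lines, pd.DataFrame):
        lines = [BattingLine(**row) for row in lines.to_dict("records")]
    rows = []
    for ln in lines:
        for stat, fn in (("OBP", compute_obp), ("BB%", compute_bb_rate), ("K%", compute_k_rate)):
            out = fn(ln)
            rows.append(
                dict(player_id=ln.player_id, league=ln.league, statistic=stat,
                     value=out.value, successes=out.successes, trials=out.trials,
                     weight=np.nan)
            )
        slg = compute_slg(ln)
        rows.append(
            dict(player_id=ln.player_id, league=ln.league, statistic="SLG",
                 value=slg.value, successes=np.nan, trials=np.nan, weight=slg.weight)
        )
    return pd.DataFrame(rows)


def pitching_statistics_table(
    lines: Iterable[PitchingLine] | pd.DataFrame,
    fip_constant: float = DEFAULT_FIP_CONSTANT,
) -> pd.DataFrame:
    """Tidy per-stint FIP table: one row per (player, league)."""
    if isinstance(lines, pd.DataFrame):
        lines = [PitchingLine(**row) for row in lines.to_dict("records")]
    rows = []
    for ln in lines:
        fip = compute_fip(ln, fip_constant)
        rows.append(
            dict(player_id=ln.player_id, league=ln.league, statistic="FIP",
                 value=fip.value, successes=np.nan, trials=np.nan, weight=fip.weight)
        )
    return pd.DataFrame(rows)
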