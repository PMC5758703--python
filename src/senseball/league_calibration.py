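"""Stage 1: league difficulty and ability-impact calibration.

The hierarchical model ``response ~ alpha_j (+/-) gamma_j * A_i`` is not
identifiable when alpha_j (league difficulty), gamma_j (ability impact in
league j) and the player abilities A_i are all free.  Identification comes
from a first stage fit to players who appeared in more than one league:
their stints tie the league scales together, and pinning the ability scale
with A_i ~ Normal(0, 1) fixes the gamma magnitudes.  The stage-1 posterior
means and SDs then become highly concentrated priors for the stage-2
covariate model.

Two sources of calibration are supported: ``calibrate_leagues`` fits the
stage-1 model to multi-league stint data, and ``load_packaged_calibration``
loads the published calibration shipped with the package (a versioned CSV;
the binomial cells are stored on the probability scale as published and
converted to the logit scale on load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .leagues import LEAGUES, STATISTICS, orientation, response_family

__all__ = [
    "LeagueCalibration",
    "IdentifiabilityError",
    "load_packaged_calibration",
    "calibrate_leagues",
]

_PACKAGED_FILE = "league_calibration_v1.csv"

#: Default prior SD for packaged calibrations, per parameter, on its own
#: scale.  The published tables print means only; 0.01 makes the stage-2
#: priors "highly concentrated" while still treating alpha_j, gamma_j as
#: parameters.
DEFAULT_PACKAGED_SD = 0.01


class IdentifiabilityError(ValueError):
    """Raised when the stint data cannot identify the league parameters."""


@dataclass
class LeagueCalibration:
    """Per-statistic concentrated priors on league parameters.

    ``alpha_mean`` is on the logit scale for binomial statistics and on the
    natural response scale for SLG/FIP.  ``gamma_mean`` is strictly
    positive: the ability impact, whose sign convention lives in the model
    orientation, not here.
    """

    statistic: str
    alpha_mean: pd.Series
    alpha_sd: pd.Series
    gamma_mean: pd.Series
    gamma_sd: pd.Series
    provenance: str = "fitted"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.provenance not in ("fitted", "packaged"):
            raise ValueError("provenance must be 'fitted' or 'packaged'")
        leagues = list(self.alpha_mean.index)
        for s in (self.alpha_sd, self.gamma_mean, self.gamma_sd):
            if list(s.index) != leagues:
                raise ValueError("all calibration series must share the same league index")
        if (self.gamma_mean <= 0).any():
            raise ValueError("gamma_mean must be positive in every league")
        if (self.alpha_sd < 0).any() or (self.gamma_sd < 0).any():
            raise ValueError("prior SDs must be nonnegative")

    @property
    def leagues(self) -> tuple[str, ...]:
        return tuple(self.alpha_mean.index)

    @property
    def family(self) -> str:
        return response_family(self.statistic)

    def alpha_response_scale(self) -> pd.Series:
        """alpha means mapped to the response scale (probabilities for rates)."""
        if self.family == "binomial":
            return pd.Series(expit(self.alpha_mean.values), index=self.alpha_mean.index)
        return self.alpha_mean.copy()

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the packaged CSV schema plus SD and provenance columns."""
        cell = self.alpha_response_scale()
        return pd.DataFrame(
            {
                "statistic": self.statistic,
                "league": list(self.leagues),
                "alpha_cell": cell.values,
                "alpha_mean": self.alpha_mean.values,
                "alpha_sd": self.alpha_sd.values,
                "gamma_mean": self.gamma_mean.values,
                "gamma_sd": self.gamma_sd.values,
                "provenance": self.provenance,
            }
        )


def load_packaged_calibration(
    statistic: str,
    alpha_sd: float = DEFAULT_PACKAGED_SD,
    gamma_sd: float = DEFAULT_PACKAGED_SD,
) -> LeagueCalibration:
    """Load the published league calibration shipped with the package.

    For binomial statistics the published table prints the inverse-logit of
    the posterior mean of alpha_j for interpretability; the logit is taken
    here so ``alpha_mean`` is always on the model's linear-predictor scale.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    with resources.files("senseball.data").joinpath(_PACKAGED_FILE).open() as fh:
        table = pd.read_csv(fh, comment="#")
    sub = table[table["statistic"] == statistic].set_index("league").loc[list(LEAGUES)]
    cells = sub["alpha_cell"].astype(float)
    if response_family(statistic) == "binomial":
        alpha = pd.Series(logit(cells.values), index=cells.index)
    else:
        alpha = cells.copy()
    leagues = alpha.index
    return LeagueCalibration(
        statistic=statistic,
        alpha_mean=alpha,
        alpha_sd=pd.Series(alpha_sd, index=leagues, dtype=float),
        gamma_mean=sub["gamma_mean"].astype(float),
        gamma_sd=pd.Series(gamma_sd, index=leagues, dtype=float),
        provenance="packaged",
        metadata={"source_file": _PACKAGED_FILE},
    )


def _check_connectivity(obs: pd.DataFrame) -> None:
    import networkx as nx

    leagues_present = sorted(obs["league"].unique(), key=LEAGUES.index)
    if len(leagues_present) < 2:
        raise IdentifiabilityError(
            "stage-1 calibration needs stints from at least two leagues; "
            f"got only {leagues_present}"
        )
    g = nx.Graph()
    g.add_nodes_from(leagues_present)
    for _, grp in obs.groupby("player_id"):
        lgs = sorted(grp["league"].unique(), key=LEAGUES.index)
        for a, b in zip(lgs, lgs[1:]):
            g.add_edge(a, b)
    components = [sorted(c, key=LEAGUES.index) for c in nx.connected_components(g)]
    if len(components) > 1:
        raise IdentifiabilityError(
            "league graph is disconnected; no multi-league players bridge the "
            f"components {components}"
        )


def calibrate_leagues(
    observations: pd.DataFrame,
    statistic: str,
    chains: int = 2,
    iterations: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    alpha_prior: tuple[float, float] = (0.0, 10.0),
    gamma_prior: tuple[float, float] = (1.0, 1.0),
    sampler: str = "pg",
) -> LeagueCalibration:
    """Fit the stage-1 model to multi-league stint observations.

    The model keeps the response layers of the hierarchy but replaces the
    covariate regression with free player abilities A_i ~ Normal(0, 1),
    which pins the latent scale and identifies gamma_j > 0.  alpha_j gets a
    vague Normal prior and gamma_j a Normal(1, 1) prior truncated to the
    positive half-line.

    ``observations`` is a tidy frame with columns ``player_id``, ``league``
    and either (``successes``, ``trials``) or (``value``, ``weight``)
    depending on the statistic's family.
    """
    from .latent_ability_model import GibbsSampler, _prepare_observations

    _check_connectivity(observations)
    family = response_family(statistic)
    s = orientation(statistic)
    y, n, pi, li, player_ids, leagues_present = _prepare_observations(
        observations, family, restrict_leagues=None
    )
    L = len(leagues_present)
    rng_root = np.random.SeedSequence(seed)
    draws_alpha, draws_gamma = [], []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c,)))
        state = GibbsSampler(
            y=y, n=n, player_index=pi, league_index=li,
            n_players=len(player_ids), family=family, orientation=s,
            mode="free",
            alpha0=np.full(L, alpha_prior[0]), alpha_sd=np.full(L, alpha_prior[1]),
            gamma0=np.full(L, gamma_prior[0]), gamma_sd=np.full(L, gamma_prior[1]),
            rng=rng, sampler=sampler,
        )
        a_buf = np.empty((iterations, L))
        g_buf = np.empty((iterations, L))
        for t in range(burn_in):
            state.sweep(adapt=True)
        for t in range(iterations):
            state.sweep()
            a_buf[t] = state.alpha
            g_buf[t] = state.gamma
        draws_alpha.append(a_buf)
        draws_gamma.append(g_buf)
    a = np.concatenate(draws_alpha, axis=0)
    g = np.concatenate(draws_gamma, axis=0)
    idx = pd.Index(leagues_present, name="league")
    return LeagueCalibration(
        statistic=statistic,
        alpha_mean=pd.Series(a.mean(axis=0), index=idx),
        alpha_sd=pd.Series(a.std(axis=0, ddof=1), index=idx),
        gamma_mean=pd.Series(np.maximum(g.mean(axis=0), 1e-12), index=idx),
        gamma_sd=pd.Series(g.std(axis=0, ddof=1), index=idx),
        provenance="fitted",
        metadata={
            "chains": chains, "iterations": iterations, "burn_in": burn_in,
            "seed": seed, "n_observations": int(len(y)),
            "n_players": int(len(player_ids)), "entropy": str(rng_root.entropy),
        },
    )
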