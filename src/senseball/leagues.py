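"""League ladder constants.

Professional baseball is organized as a ladder of six league levels, from
Rookie ball up through the Major Leagues.  League codes are ordered by
competitive level; several operations (adjacent-league stints, monotone
difficulty checks) rely on this ordering.
"""

from __future__ import annotations

LEAGUES: tuple[str, ...] = ("Rookie", "A", "AdvA", "AA", "AAA", "MLB")
LEAGUE_INDEX: dict[str, int] = {lg: i for i, lg in enumerate(LEAGUES)}

BINOMIAL_STATISTICS: tuple[str, ...] = ("OBP", "BB%", "K%")
NORMAL_STATISTICS: tuple[str, ...] = ("SLG", "FIP")
STATISTICS: tuple[str, ...] = BINOMIAL_STATISTICS + NORMAL_STATISTICS

BATTER_STATISTICS: tuple[str, ...] = ("OBP", "BB%", "K%", "SLG")
PITCHER_STATISTICS: tuple[str, ...] = ("FIP",)

#: Statistics for which higher latent ability *lowers* the response
#: (striking out and allowing runs are bad outcomes).  The linear predictor
#: for these is alpha_j - gamma_j * A_i; for all others alpha_j + gamma_j * A_i.
NEGATIVE_ORIENTATION: frozenset[str] = frozenset({"K%", "FIP"})


def orientation(statistic: str) -> int:
    """Sign on the gamma_j * A_i term of the linear predictor (+1 or -1)."""
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    return -1 if statistic in NEGATIVE_ORIENTATION else +1


def response_family(statistic: str) -> str:
    """'binomial' for the rate statistics, 'normal' for the averages."""
    if statistic in BINOMIAL_STATISTICS:
        return "binomial"
    if statistic in NORMAL_STATISTICS:
        return "normal"
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
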