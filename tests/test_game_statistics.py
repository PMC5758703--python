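"""Statistic arithmetic, eligibility filtering, and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from senseball.game_statistics import (
    BattingLine,
    PitchingLine,
    DegenerateInputError,
    batting_statistics_table,
    build_design_matrix,
    compute_bb_rate,
    compute_fip,
    compute_k_rate,
    compute_obp,
    compute_slg,
    eligibility_filter,
    TASK_COLUMNS,
)


def bline(**kw):
    base = dict(
        player_id="P1", league="AAA", hits=0, walks=0, hit_by_pitch=0,
        at_bats=50, sacrifice_flies=0, plate_appearances=60, strikeouts=0,
        total_bases=0,
    )
    base.update(kw)
    return BattingLine(**base)


class TestRateDefinitions:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(hits=30, walks=10, hit_by_pitch=2, at_bats=100, sacrifice_flies=3,
                  plate_appearances=120, total_bases=40), 42 / 115),
            (dict(hits=0, walks=0, hit_by_pitch=0, at_bats=50, sacrifice_flies=0), 0.0),
        ],
    )
    def test_obp_values(self, kw, expected):
        out = compute_obp(bline(**kw))
        assert out.value == pytest.approx(expected, abs=1e-12)
        assert out.successes / out.trials == out.value

    def test_obp_zero_denominator_raises(self):
        line = bline(at_bats=0, plate_appearances=0)
        with pytest.raises(DegenerateInputError):
            compute_obp(line)

    def test_walk_and_strikeout_rates(self):
        line = bline(walks=10, plate_appearances=100, at_bats=80)
        assert compute_bb_rate(line).value == pytest.approx(0.10)
        assert compute_k_rate(line).value == 0.0
        full = bline(walks=100, plate_appearances=100, at_bats=0, hits=0,
                     strikeouts=0)
        assert compute_bb_rate(full).value == 1.0  # walk-every-time boundary

    def test_rates_error_on_zero_pa(self):
        line = bline(plate_appearances=0, at_bats=0)
        with pytest.raises(DegenerateInputError):
            compute_bb_rate(line)
        with pytest.raises(DegenerateInputError):
            compute_k_rate(line)

    @pytest.mark.parametrize(
        "tb, ab, expected",
        [(180, 400, 0.45), (0, 400, 0.0), (4, 1, 4.0)],
    )
    def test_slg(self, tb, ab, expected):
        line = bline(at_bats=ab, total_bases=tb, hits=min(1, tb),
                     plate_appearances=max(ab, 60))
        out = compute_slg(line)
        assert out.value == pytest.approx(expected)
        assert out.weight == ab

    def test_slg_zero_at_bats_raises(self):
        with pytest.raises(DegenerateInputError):
            compute_slg(bline(at_bats=0))


class TestFIP:
    def test_constant_only(self):
        line = PitchingLine("P1", "MLB", home_runs=0, walks=0, hit_by_pitch=0,
                            strikeouts=0, innings_pitched=9.0)
        assert compute_fip(line, 3.10).value == pytest.approx(3.10)

    def test_standard_line(self):
        line = PitchingLine("P1", "MLB", home_runs=1, walks=3, hit_by_pitch=0,
                            strikeouts=9, innings_pitched=9.0)
        assert compute_fip(line, 3.10).value == pytest.approx((13 + 9 - 18) / 9 + 3.10)

    def test_negative_fip_allowed(self):
        line = PitchingLine("P1", "MLB", home_runs=0, walks=0, hit_by_pitch=0,
                            strikeouts=60, innings_pitched=20.0)
        assert compute_fip(line, 3.10).value < 0

    def test_zero_innings_raises(self):
        line = PitchingLine("P1", "MLB", home_runs=0, walks=0, hit_by_pitch=0,
                            strikeouts=0, innings_pitched=0.0)
        with pytest.raises(DegenerateInputError):
            compute_fip(line)


class TestEligibility:
    def test_strict_boundary(self):
        frame = pd.DataFrame({
            "player_id": ["a", "b", "c"], "at_bats": [30, 31, 200],
        })
        kept = eligibility_filter(frame, role="batter")
        assert list(kept["player_id"]) == ["b", "c"]
        ip = pd.DataFrame({"player_id": ["d", "e"], "innings_pitched": [30.0, 30.1]})
        assert list(eligibility_filter(ip, role="pitcher")["player_id"]) == ["e"]

    def test_idempotent(self):
        frame = pd.DataFrame({"player_id": list("abcd"), "at_bats": [10, 31, 45, 30]})
        once = eligibility_filter(frame, role="batter")
        twice = eligibility_filter(once, role="batter")
        pd.testing.assert_frame_equal(once, twice)

    def test_object_interface(self):
        lines = [bline(player_id=p, at_bats=ab, plate_appearances=ab + 5)
                 for p, ab in [("a", 30), ("b", 31)]]
        kept = eligibility_filter(lines, role="batter")
        assert [ln.player_id for ln in kept] == ["b"]


@st.composite
def counting_lines(draw):
    ab = draw(st.integers(0, 600))
    hits = draw(st.integers(0, ab))
    walks = draw(st.integers(0, 100))
    hbp = draw(st.integers(0, 10))
    sf = draw(st.integers(0, 10))
    k = draw(st.integers(0, ab))
    extra = draw(st.integers(0, 20))
    pa = ab + walks + hbp + sf + extra
    tb = draw(st.integers(hits, min(4 * ab, hits + 3 * ab) if ab else 0))
    return BattingLine("P", "A", hits, walks, hbp, ab, sf, max(pa, walks + k),
                       k, tb)


@given(counting_lines())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_rates_bounded_and_consistent(line):
    """All rate statistics stay in [0,1] and their count pairs reproduce them."""
    for fn in (compute_obp, compute_bb_rate, compute_k_rate):
        try:
            out = fn(line)
        except DegenerateInputError:
            continue
        assert 0.0 <= out.value <= 1.0
        assert out.successes <= out.trials
        assert out.value == out.successes / out.trials


class TestDesignMatrix:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(3)
        n = 40
        ids = pd.Index([f"P{i}" for i in range(n)], name="player_id")
        battery = pd.DataFrame(
            {t: rng.normal(50, 10, n) for t in TASK_COLUMNS}, index=ids
        )
        battery["depth_perception"] = rng.lognormal(3.0, 0.5, n)
        ages = pd.Series(rng.normal(23, 3, n), index=ids)
        positions = pd.Series(
            rng.choice(["catcher", "infielder", "outfielder"], n), index=ids
        )
        return battery, ages, positions

    def test_standardized_columns(self, cohort):
        battery, ages, positions = cohort
        dm = build_design_matrix(battery, ages, positions, role="batter")
        for col in dm.standardization.index:
            vals = dm.X[col]
            assert vals.mean() == pytest.approx(0.0, abs=1e-10)
            assert vals.std(ddof=1) == pytest.approx(1.0, rel=1e-10)
        assert "go_no_go" not in dm.X.columns
        assert set(dm.X.columns) >= {"intercept", "is_catcher", "is_infielder"}
        # dummies are untouched 0/1 columns
        assert set(dm.X["is_catcher"].unique()) <= {0.0, 1.0}

    def test_missing_depth_flagged_once(self, cohort):
        battery, ages, positions = cohort
        battery = battery.copy()
        battery.iloc[0, battery.columns.get_loc("depth_perception")] = np.nan
        dm = build_design_matrix(battery, ages, positions, role="batter")
        flagged = dm.missing_mask.iloc[0]
        assert flagged.sum() == 1
        assert flagged["log_depth_perception"]
        assert dm.X.iloc[0]["log_depth_perception"] == 0.0
        # standardization excludes the missing entry
        col = np.log(battery["depth_perception"].dropna())
        assert dm.standardization.loc["log_depth_perception", "mean"] == pytest.approx(col.mean())

    def test_zero_variance_column_named(self, cohort):
        battery, ages, positions = cohort
        ages = pd.Series(25.0, index=ages.index)
        with pytest.raises(DegenerateInputError, match="age"):
            build_design_matrix(battery, ages, positions, role="batter")

    def test_nonpositive_depth_perception_rejected(self, cohort):
        battery, ages, positions = cohort
        battery = battery.copy()
        battery.iloc[1, battery.columns.get_loc("depth_perception")] = -2.0
        with pytest.raises(DegenerateInputError, match="depth"):
            build_design_matrix(battery, ages, positions, role="batter")

    def test_row_permutation_commutes(self, cohort):
        battery, ages, positions = cohort
        dm = build_design_matrix(battery, ages, positions, role="batter")
        perm = battery.index[::-1]
        dm2 = build_design_matrix(
            battery.loc[perm], ages.loc[perm], positions.loc[perm], role="batter"
        )
        pd.testing.assert_frame_equal(dm.X.loc[perm], dm2.X)

    def test_pitcher_design_has_no_position_dummies(self, cohort):
        battery, ages, _ = cohort
        dm = build_design_matrix(battery, ages, role="pitcher")
        assert "is_catcher" not in dm.X.columns
        assert "is_infielder" not in dm.X.columns
        assert dm.reduced().columns == ("intercept", "age")


def test_batting_statistics_table_shapes():
    lines = [bline(player_id="a", hits=40, walks=12, at_bats=150,
                   plate_appearances=170, strikeouts=30, total_bases=60)]
    table = batting_statistics_table(lines)
    assert set(table["statistic"]) == {"OBP", "BB%", "K%", "SLG"}
    slg = table[table["statistic"] == "SLG"].iloc[0]
    assert slg["weight"] == 150
    obp = table[table["statistic"] == "OBP"].iloc[0]
    assert obp["successes"] == 52
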