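# Data dictionary

Column names for the CSV surfaces the package reads and writes.  All files
are plain CSV with a header row; league codes are `Rookie`, `A`, `AdvA`,
`AA`, `AAA`, `MLB`.

## Batting lines (`batting_lines.csv`) — one row per (player, league) stint

| column | type | meaning |
| --- | --- | --- |
| `player_id` | str | stable player identifier |
| `league` | str | league code for the stint |
| `hits` | int | hits (≤ `at_bats`) |
| `walks` | int | bases on balls |
| `hit_by_pitch` | int | times hit by a pitch |
| `at_bats` | int | official at-bats |
| `sacrifice_flies` | int | sacrifice flies |
| `plate_appearances` | int | plate appearances (≥ `walks` + `strikeouts`) |
| `strikeouts` | int | strikeouts (≤ `at_bats`) |
| `total_bases` | int | total bases (≥ `hits`) |

## Pitching lines (`pitching_lines.csv`) — one row per (player, league) stint

| column | type | meaning |
| --- | --- | --- |
| `player_id`, `league` | str | as above |
| `home_runs` | int | home runs allowed |
| `walks` | int | walks allowed |
| `hit_by_pitch` | int | batters hit |
| `strikeouts` | int | strikeouts recorded |
| `innings_pitched` | float | real innings: 31.2 "baseball" innings is 31 + 2/3 ≈ 31.667 |

## Players (`players.csv`) — one row per player

| column | type | meaning |
| --- | --- | --- |
| `player_id` | str | identifier |
| `role` | str | `batter` or `pitcher` |
| `age` | float | age in years at assessment |
| `position` | str | `catcher` / `infielder` / `outfielder` (batters); `pitcher` otherwise |

## Battery (`battery.csv`) — one row per player, raw task scores

`player_id` plus the nine task columns in their native units:
`visual_clarity`, `contrast_sensitivity`, `depth_perception` (strictly
positive; may be empty = missing), `near_far_quickness`, `target_capture`,
`perception_span`, `eye_hand_coordination`, `go_no_go`, `reaction_time`.

## Tidy statistics / observations (`outcomes.csv`, `stats` output)

One row per (player, league, statistic).

| column | type | meaning |
| --- | --- | --- |
| `player_id`, `league` | str | as above |
| `statistic` | str | `OBP`, `BB%`, `K%`, `SLG`, `FIP` |
| `value` | float | the statistic's value |
| `successes`, `trials` | int | count pair (rate statistics only) |
| `weight` | float | opportunity count (SLG: at-bats; FIP: innings) |

Synthetic outcomes additionally carry the generative truth columns
`linear_predictor`, `eta`, `p`, `mu`.

## Calibration (`league_calibration_v1.csv` schema + fitted output)

| column | type | meaning |
| --- | --- | --- |
| `statistic`, `league` | str | as above |
| `alpha_cell` | float | league level on the published scale (probability for rates, natural for SLG/FIP) |
| `alpha_mean`, `alpha_sd` | float | league difficulty prior, model (logit/natural) scale |
| `gamma_mean`, `gamma_sd` | float | ability-impact prior (strictly positive mean) |
| `provenance` | str | `packaged` or `fitted` |

## Chain sets (`chains_*.csv`)

`#`-prefixed YAML metadata header (statistic, coefficient names, leagues,
settings echo, seeds, observation table), then one row per retained draw:
`chain`, `iteration`, `beta:<coefficient>`, `tau`, `sigma2` (normal family),
`alpha:<league>`, `gamma:<league>`, `eta:<obs index>`, `m:<obs index>`
(regression-level linear predictor), `imputed:<player>:<column>`.
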