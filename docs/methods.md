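# Methods

This note records the model, the estimation machinery, the synthetic-data
design, and the judgement calls made where the design was genuinely open.

## Model and assumptions

Five statistics are modeled separately with a shared two-layer hierarchy.
A stint — one player's aggregate within one league — is the observation
unit.  Rate statistics (OBP, BB%, K%) are binomial over their opportunity
counts with a logit-normal latent layer; per-opportunity averages (SLG,
FIP) are normal with sampling variance `sigma^2 / N_ij`, which leans on the
central limit theorem and is why stints need more than 30 at-bats or
innings pitched (strict inequality, applied per stint; a player stays in
the pool if any stint survives).

Key structural assumptions:

* **Latent ability is scalar and linear in covariates**: `A_i = x_i' beta`
  with eight standardized task scores (depth perception logged first —
  the raw scores are strongly right-skewed), standardized age (linear;
  survivorship makes the age effect positive), and catcher/infielder
  dummies against an outfielder reference.  Go/no-go is excluded: it is
  nearly collinear with eye-hand coordination.
* **Orientation**: `gamma_j > 0` everywhere, and the linear predictor is
  `alpha_j + gamma_j A_i` except for K% and FIP where it is
  `alpha_j − gamma_j A_i`.  The negative orientation for strikeouts is
  forced by the published worked example: a positive perception-span
  coefficient corresponds to a *reduced* predicted strikeout rate
  (23.2% → 21.2%), which is only consistent with ability lowering the
  strikeout probability.  For FIP the same logic applies (runs allowed
  are bad); the published per-league impact values are orientation-neutral.
* **Identification**: with `alpha_j`, `gamma_j`, `A_i` all free the model
  is unidentified.  Stage 1 fits the same response layers to multi-league
  players with free abilities `A_i ~ N(0, 1)` (pinning the latent scale),
  vague `alpha_j ~ N(0, 10^2)` and `gamma_j ~ N(1, 1)` truncated positive.
  Stage 2 then treats the stage-1 posterior means/SDs as highly
  concentrated priors.  Stage-1 calibration is estimated independently per
  statistic.  A connectivity check (league graph with edges from
  multi-league players) rejects unidentifiable inputs up front.
* **Standardization pool**: covariates are standardized within each role's
  analyzed (post-filter) pool, and the mean/SD pairs are persisted so
  prediction-time profiles reuse the training scaling.  Batters and
  pitchers are standardized separately because the models are fit
  separately.

## Priors and estimation

Defaults (all configurable on `ModelSpec`): `beta ~ N(0, 10^2)` i.i.d.
(non-informative on the standardized scale), `tau ~ Gamma(0.001, 0.001)`,
`sigma^2 ~ Inverse-Gamma(0.001, 0.001)`.  Packaged calibrations carry
prior SDs of 0.01 per parameter on its own scale — "highly concentrated"
while still letting `alpha_j`, `gamma_j` be sampled; fitted calibrations
carry their stage-1 posterior SDs.  A `league_params="fixed"` mode pins
them at the prior means instead.

The sampler is a systematic-scan Gibbs sampler.  The binomial-logit layer
is made conjugate by Pólya-Gamma augmentation; every other conditional
(latent logits/means, `beta`, league parameters, `tau`, `sigma^2`, missing
covariates) is a standard weighted-normal, gamma, inverse-gamma or
truncated-normal draw.  Pólya-Gamma variates are drawn in-package from the
truncated sum-of-gammas representation (100 terms) with an analytic
tail-mean correction; the truncation's variance deficit decays as the cube
of the term count and is negligible at the trial counts involved (all
above 30).  An augmentation-free alternative — adaptive random-walk
Metropolis on each logit, tuned toward ~30% acceptance during burn-in —
is provided as `sampler="mh"`, and the test suite requires the two
samplers to agree (KS < 0.05 per coefficient marginal) on a shared toy.
Correctness is additionally enforced by a joint-distribution
(marginal-conditional versus successive-conditional) simulation test and
by dense-grid quadrature on a single-coefficient toy.

Missing depth-perception scores get independent standard-normal priors on
the standardized scale and are drawn inside the sampler from their
conjugate normal conditionals; a player with no surviving stints draws
from the prior alone.

Initialization is deterministic: `beta = 0`, `tau = 1`, `sigma^2` at the
sample variance, logits at the empirical logit with a ±0.5 continuity
correction, missing covariates at 0.  Chains derive per-chain seeds from
the master seed through fixed spawn keys, so every fit is bit-reproducible.
Default run length mirrors the production setting: 3 chains × 10,000
iterations after 1,000 burn-in.  A collapsed mode (`overdispersed=False`,
i.e. `tau^{-1} = 0`) removes the latent layer; in the normal family the
`beta` conditional there *is* the exact weighted-Bayes-regression
posterior, which the tests exploit as a closed-form oracle.

## Model comparison and checking

WAIC is computed on the deviance scale, `−2(lppd − p_waic)`, with the
variance form of `p_waic`, pointwise over stints, via stable
log-sum-exp.  The full model (sensorimotor tasks + controls) is compared
with the reduced model (intercept, age, position dummies — the same code
path with a smaller design) per statistic; `delta = full − reduced < 0`
reads "the sensorimotor variables add predictive power".

Convergence is summarized by split-chain R-hat (own implementation; the
degenerate all-constant case returns 1.0) with a conventional 1.1
threshold, and bulk ESS (delegated to arviz in the test extra).
Posterior predictive checks are realized-discrepancy checks: replicates
are simulated through the full generative path (fresh latent layer from
the regression mean, then outcomes), and the reported p-value is
`P(D_rep ≥ D_obs)` with ties counting toward the p-value (a constant
discrepancy gives exactly 1.0).  Two discrepancies ship by default —
the maximum absolute league-mean error against the regression-level
expectation, and the maximum absolute cell error — and callables plug in.

## Synthetic cohorts

The generator reproduces the study conditions as defaults: 141 batters
and 111 pitchers; ages Normal(22.7, 3.9) clipped to 17–37 for batters and
Normal(23.7, 3.6) clipped to 18–39 for pitchers; positions multinomial at
19/65/57 (catcher/infielder/outfielder); league membership frequencies
matching the published per-league counts, with 30% of players receiving a
second, adjacent-league stint (the published totals imply multi-league
players but not their joint distribution; 30% keeps the league graph
well-connected for stage 1); exactly round(rate·n) missing
depth-perception scores (four per role at the defaults), missing
completely at random.  Task scores are a correlated Gaussian latent field
mapped to plausible native scales, with depth perception log-normal so
the log transform is meaningful; the published work does not report the
task covariance, so the default is a modest common correlation of 0.2
with go/no-go–eye-hand at 0.7, configurable.

Generative parameters default to the study's published values where they
exist: league difficulty and impact from the packaged calibration, and
coefficient vectors for OBP/BB%/K% from the published posterior means.
Where no value is published we chose once: `tau = 25` for the rate
statistics (logit-scale overdispersion SD 0.2, consistent with the
published coefficient uncertainties at this sample size), `tau = 700` and
`sigma^2 = 0.6` for SLG, `tau = 1.2` and `sigma^2 = 60` for FIP;
opportunity counts uniform on 50–600 plate appearances and 31–180
innings.  SLG and FIP default to zero sensorimotor coefficients (the
study found no signal there) with an age effect of 0.3.

Outcomes are drawn from the hierarchy's exact law, so recovery tests have
exact ground truth.  A separate composer writes raw counting lines
(hits, walks, at-bats, …) consistent with the drawn statistics up to
integer rounding and light rebalancing — it exercises the CSV ingest
path, not the estimator.  What the generator does *not* emulate: within-
season ability drift, park and era effects, non-random missingness,
pitch-level structure, and any real covariance among the five statistics
beyond their shared ability covariates.  Passing recovery tests therefore
certify the estimator under the model's own assumptions, not robustness
to their violation.

## Problem sizes in the test suite

The replicated studies run at deliberately reduced MCMC lengths chosen as
the package's own trade-off between statistical resolution and runtime:
parameter recovery uses 20 cohorts of 141 batters with 2 chains × 600
iterations (300 burn-in) at the published coefficient truth; WAIC
discrimination uses 20 signal and 20 null cohorts at 2 × 400 (200), with
the signal arm's eight task coefficients doubled so the sensorimotor
signal carries latent variance comparable to the overdispersion layer (at
the published means the expected full-vs-reduced WAIC gap under this
generator is only about −1, within cohort-to-cohort noise — a genuinely
marginal regime, which is worth knowing when interpreting real fits); the grid-quadrature comparison uses 3 × 40,000
single-observation sweeps; the sampler cross-validation 3 × 12,000 on a
10-player toy, thinned by 5.  At these lengths the Monte Carlo error is
comfortably below every acceptance margin asserted in the tests.

## Known limitations

* The stage-1 model here is the minimal identified variant (free standard
  -normal abilities); richer stage-1 choices (shared `gamma` across
  statistics, year effects) are possible but unimplemented.
* Packaged calibration SDs are a convention (0.01), not published values.
* The FIP constant is configuration (default 3.10); published FIP tables
  depend on the league-year constant actually used.
* WAIC is reported without the leave-one-out refinements (Pareto-smoothed
  importance sampling); for these sample sizes the plain estimator is the
  published choice.
* Real-data coefficient tables cannot be reproduced without the
  proprietary cohort; the packaged copies of the published values are
  inputs for prediction, not outputs of this package's fits.
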