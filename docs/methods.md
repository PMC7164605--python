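# Methods

## Estimand and model

The target is the causal effect of cumulative competition load (career total
games played, `g`) on the weekly hazard of a time-loss event, allowing the
effect to be modified by age (`a`).  The structural model for the weekly
log-hazard is

    log h(t | a, g) = log h0(t) + beta1 * g + beta2 * a * g + nu1 * (a - alpha1 - alpha2 * g)

estimated as a discrete-time hazard by pooled logistic regression on
person-week records.  At weekly event rates near 3% the logit and log links
are practically indistinguishable, and odds ratios from the pooled logistic
are reported as hazard ratios.

The age main effect is not entered as raw age.  Age is replaced by its
residual from a weighted linear conditional-mean model given cumulative load
(`E[a|g] = alpha1 + alpha2 g`, fitted with the combined weights).  This
"regression with residuals" construction keeps the nuisance age term
mean-zero given treatment history and avoids the over-adjustment/collider
bias of conditioning directly on a moderator correlated with exposure
history.

**Contrast reporting.**  The design columns `{g, a*g, a - alpha1 - alpha2*g}`
span the same space as `{g, a*g, a}`.  Consequently the fitted `beta1`
absorbs `nu1*alpha2` relative to the raw-age parameterization, and the only
parameterization-invariant "same age, more load" contrast is

    HR(delta_g | a) = exp(delta_g * (beta1 + beta2 * a - nu1 * alpha2))

This fixed-age contrast is what `SNMMFit.hr_per_1000` and all per-1,000-game
reporting use; simulation confirms the uncorrected functional
`exp(delta_g*(beta1 + beta2*a))` is biased upward by `nu1*alpha2*delta_g`
whenever age predicts load.  The uncorrected "blip" functional is still
exposed (`effects.hazard_ratio_direct`) alongside the vs-reference contrast,
which at equal ages reduces exactly to the fixed-age contrast.

## Weights

The treatment at week `t` is the week's game load.  Its conditional density
is modelled as homoscedastic normal around a linear mean: the denominator
conditions on lagged load, the back-to-back indicator, the prior-long-
time-loss indicator, and a natural cubic spline (4 df) in rating; the
numerator conditions only on lagged load and lagged age.  The per-week
stabilization factor is the full normal density ratio (including the
`sigma/sigma0` Jacobian, which the equal-sigma special case reduces to a
ratio of standard-normal kernels), and the weight at week `t` is the running
product of factors from the player's baseline.  Censoring weights use
logistic models of the uncensored indicator with the same two right-hand
sides.  The combined weight is their product.

Numerical conventions:

* **First baseline week.**  The first record of each player has no observed
  history; both conditional densities degenerate to the same marginal, so
  its factor is exactly 1 and first records are excluded from weight-model
  fitting.  (Imputing a zero lagged load instead creates a high-leverage
  extrapolation point that only the denominator can fit — via the
  back-to-back indicator — and injects a spurious -0.7 mean log-weight at
  week 1.)
* Weight models are fitted by least squares / IRLS; with a Gaussian family
  and an independence working structure clustered on players the point
  estimates coincide with GEE, and only point estimates and the residual SD
  enter the weights (all inference is by cluster bootstrap).  The IRLS uses
  deviance-guarded step halving, which heavy cumulative weights otherwise
  destabilize.
* A single global residual SD per model, no weight truncation by default
  (optional percentile truncation is deliberately not applied anywhere in
  the shipped analyses), cumulative log-weights floored at log(1e-12) with
  a count of floored records.
* With fewer than 20 censoring events the covariate-conditional censoring
  models are quasi-separated and unidentifiable; both sides then collapse
  to the marginal rate (unit censoring weights).
* Indicator columns that are constant in a (re)sample are dropped from that
  fit; spline blocks and intercepts are always retained.

**Balance.**  The population standard bias at week `t` splits that week's
records at the (weighted) median of observed weekly load and scales the
absolute high-low covariate mean difference by the pooled unweighted SD.
This median-split operationalization is a documented choice: no standard
PSB definition exists for a continuous exposure.  PSB <= 0.25 is treated as
adequate balance; weeks with fewer than 20 records are skipped.

## Outcome definition

Between-competition gaps are counted as days strictly between competition
spells (a spell is 1 day for point-event data, 7 days for weekly panels),
and each gap belongs to the calendar month in which it commenced.  The
expected maximum gap per player-month comes from a REML linear mixed model
of monthly maximum gaps with month fixed effects and a player random
intercept, trained on players with at least three seasons at rating 2300+
(a season = a calendar year with at least one week at or above the
threshold); other players receive the pooled month mean.  Expectations are
clamped at zero.  A per-month random-effect structure with unstructured
covariance is available behind a flag but needs many seasons per player to
be stable and is not the default.  The mixed model is optimized with
Powell's method: near-zero between-player variance puts the REML optimum on
a boundary where gradient optimizers can stall at a spurious solution.

A month whose maximum gap is at least 14 days longer than expected (28 days
for January, which absorbs the off-season) flags a time-loss event,
anchored to the last competition week preceding the gap — the outcome is
determined at the end of each competition week.  Terminal records are
classified by registry status when the last match is a year or more before
the window end: retired/banned -> censored (retirement is a competing
risk), still-active -> unintended absence (event), unknown -> censored and
reported.

Eligibility (peak rating >= 2300 during the observation period) is a
career-level property; the peak is attached as a player-level column before
any row filtering so that the eligibility and baseline filters commute.

## Synthetic data generator

One row per player per competition week.  Latent ability (rating points)
drives weekly competition probability, mean weekly games, the time-loss
hazard (protective), and optionally retirement; measured rating is ability
plus slowly varying AR(1) noise.  Weekly games follow an AR(1) around a
player-specific mean (ability effect + a persistent independent "schedule
style"); this keeps the population treatment model exactly linear in lagged
load, so the fitted weight models are correctly specified by construction.
The weekly hazard is logistic with load centered at 10,000 games and age at
25 years (the reference player), so `base_weekly_hazard` is the reference
player's weekly event probability.  Events draw a lognormal recovery
absence; retirement is a weekly logistic hazard in age (and optionally
ability) that terminates the career.  The off-season (weeks 49-52, plus a
reduced week 1) nearly suspends competition.  A fixed seed yields a
byte-identical panel.

Scenario presets are the study conditions and are fixed:

* `null` — no causal effect, no confounding; 75 players x 1.3 years.  Sized
  so percentile cluster-bootstrap CIs hold nominal coverage (at 50 clusters
  coverage degrades to ~91% — a property of the bootstrap, not the
  estimator).
* `confounded` — true fixed-age effect HR 1.05 per 1,000 games; ability adds
  ~0.035 games/week per rating point to load and is strongly protective
  (-0.01 log-hazard per point); 389 players entering the risk pool at 8,000
  games for ~110 weeks.  High load persistence (autocorrelation 0.93) keeps
  the conditional rating signal — and hence weight variance — small while
  the marginal rating-load correlation stays large, which is what makes the
  published imbalance pattern (unweighted rating PSB > 0.25 early, weighted
  < 0.25) reproducible together with stable weights.
* `paper_calibrated` — 860 full careers over a 15.2-year window with the
  calibrated truth (below).  After the eligibility and baseline filters the
  analysis cohort has ~300 players and ~55-60k competition weeks, a ~3%
  weekly event rate, mean rating ~2360, and load quintiles running from
  ~9,100 games at age ~25.4 to ~22,000 games at age ~31.7.  Reproducing the
  tight top-quintile load with the strong age gradient requires full
  (unstaggered) careers, ability-dependent retirement (journeymen leave
  early, stars persist), and a mild seniority trend in games per week; it
  also caps how strong per-week confounding can be, so this preset's naive
  estimate is attenuated rather than sign-reversed — the sign reversal is a
  property of the `confounded` scenario.

The calibrated truth ties both headline contrasts together:
`beta1 = ln(1.05)/1000` per game at the age-25 reference and
`beta2 = (ln(1.65/1.33)/3000 - ln(1.05)/1000)/4 ≈ 5.77e-6` per game-year,
so the per-1,000-game fixed-age hazard ratio is 1.05 at age 25 and the
+3,000-game contrast at age 29 is 1.65/1.33 ≈ 1.241.

What the generator does *not* emulate: tournament-block scheduling (weekly
competition is conditionally independent given the season, so back-to-back
rates are higher than real calendars), match-level structure (surfaces,
scores, rating updates from results), training load, and any unmeasured
confounding unless the optional frailty term is switched on.  Passing tests
therefore demonstrate correctness of the estimation machinery under the
assumed causal structure, not robustness to violations of sequential
ignorability.

## Power calculation

The design statement — 80% power to detect a 20% relative risk increase in
the top load quartile of 389 players over a 3% weekly base rate with "a
traditional survival analysis" — is reproduced by Monte Carlo with the
player-season as the survival unit: ~4.9 seasons per player (fixed
allocation, as a design calculation assumes) of ~29.3 competition weeks
each (totalling ~55,773 weeks), time to first event within season, and a
log-rank test at alpha 0.05.  With one time-to-first-event per *player*
instead, at most 389 events are available and the log-rank noncentrality
`ln(1.2)*sqrt(389*3/16) ≈ 1.55` caps power near 34%, far below the
published figure, so the player-season unit is the only reading of "a
traditional survival analysis" consistent with the stated power.  The
simulated power is ~0.79-0.84; the null rejection rate is ~5%.

## Problem sizes and numerical checks

Replication and calibration checks run at these sizes (chosen as the
package's study conditions): power, 1,000 simulations; main-effect
recovery, 200 confounded panels of ~100 players x ~100 weeks; interaction
recovery, one ~400-player, 10-season panel validated against the
Monte-Carlo spread of 50 replicates; sign reversal, 100 replicates at the
full confounded preset; CI calibration, 500 null replicates with B = 200
bootstrap resamples each.  The bootstrap resampling unit is always the
player.  Estimated coefficients are cross-checked against statsmodels
(GEE/GLM/WLS) to 1e-7 or better on shared designs; the stabilized-weight
cumulative products are verified against record-by-record brute force to
1e-12.

## Known limitations

* The logistic (rather than log-linear) hazard makes reported ratios odds
  ratios; at 3% weekly rates the discrepancy is second-order.
* Percentile bootstrap CIs need ~50+ clusters; smaller cohorts undercover.
* The expected-gap mixed model ignores within-player month-to-month
  correlation beyond the random intercept unless the per-month structure is
  enabled.
* Long follow-up (200+ weeks) lets cumulative weights drift (geometrically
  decaying means, growing dispersion), which inflates the variance of
  late-week diagnostics; the package reports but does not truncate.
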