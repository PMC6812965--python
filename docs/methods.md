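# Methods

This note documents the model, the synthetic-data generator, the estimation
and inference choices, and the known limitations of the package.

## The feedback-contingent choice model

A player repeatedly chooses between two action rules against an opponent
whose only summarised property is the probability `p_os` of switching rules
between consecutive trials.  The switch log-odds on trial *n* are

```
logit P(switch_n) = wl · os · (ms + sm · (1 − wl)/2) − pe − wl · ss
os = ln(p_os / (1 − p_os)),   wl = +1 (win on n−1) / −1 (loss on n−1)
```

Assumptions built into this form:

* **Lag-1 sufficiency.** Only the previous trial's feedback gates the
  strategy; all longer-range structure enters through `p_os`.
* **Log-odds linearity.** The opponent's rate acts through its log-odds,
  so probability matching is the unit-slope special case (`ms = 1`,
  other parameters 0 gives `P(switch) = p_os` after wins).
* **Role symmetry.** Fox and rabbit face the same decision problem: for
  either role, following a win the incentive-compatible response is to
  switch with the opponent's switch probability, and following a loss
  with its complement.  The model therefore carries no role term.
* **Errors are losses.** Action errors produce loss feedback and enter the
  model only through `wl`.

Interpretation of the parameters (all in log-odds units): `ms` is the
post-win slope on `os`; `ms + sm` is the post-loss slope *after recoding
post-loss rates* `p → 1 − p` (the "reversed-label" axis), so `sm < 0` is
loss-contingent suppression of the opponent model; `pe > 0` biases toward
repeating the previous rule irrespective of feedback; `ss > 0` is
win-stay/lose-shift.  Derived slopes are exposed as
`ChoiceParams.post_win_slope` / `post_loss_slope`.

First trials of blocks have no previous feedback; they are excluded from
every fit and conditional analysis, and the simulator draws them uniformly.

## Estimation

**Condition averages** (`ConditionAverageModel`).  The observed mean switch
rate per (opponent rate × previous feedback) cell is fit by minimising the
sum of squared deviations from the model's predicted probabilities.  Cells
have near-equal trial counts in the balanced designs, so the objective is
unweighted by default; `weight_by_n=True` enables count weighting.  The
optimiser is a derivative-free simplex started at (0.5, −0.3, 0.1, 0.2)
with five jittered restarts (fixed restart seed), followed by a
Levenberg–Marquardt polish; no parameter bounds.  The polish makes
noise-free inversion exact to ~1e−12.  R² is computed about the grand mean
of the observed cells.  Identifiability requires at least four distinct
cells; rank of the residual Jacobian is checked at the solution and flagged
if deficient.  Uncertainty is a residual bootstrap (199 resamples, fixed
seed, refit from the solution, percentile 95% intervals).  Published "±"
intervals for this model family are method-unspecified; the bootstrap
intervals here are not claimed to match any externally reported ones.

**Trial sequences** (`TrialwiseModel`).  Given the transformed regressors
`[wl·os, wl·os·(1−wl)/2, −1, −wl]` the model is linear in its parameters,
so the Bernoulli ML fit is an ordinary logistic regression (statsmodels
`Logit`, Newton), with Wald standard errors from the observed information.
Degenerate all-switch/all-repeat sequences and rank-deficient designs
(e.g. constant `wl` and constant `p_os`, which collapses the model columns)
are flagged — `converged=False`, a runtime warning — never silently
accepted.

**Running opponent estimate.**  When no programmed rate exists (human or
simulated dyads), `p_os` is a within-block running average of the partner's
observed switches, available strictly before the current trial.  The
estimate is a Beta-style mean: the previous block's final estimate carries
over as one pseudo-observation (first block starts from 0.5), and a
symmetric 0.5/0.5 Laplace cushion keeps the estimate off {0, 1}; the
output is additionally clipped to [0.01, 0.99] so `os` stays finite.  The
carry-over weight and the smoothing are parameters because the weighting of
prior-block knowledge is a genuinely open design choice; the default
(weight 1, smoothing 0.5) was fixed once and is used everywhere.

## The synthetic-data generator

`simulate_session` runs the game closed-loop: per block, an opponent rule
sequence with the programmed switch rate (first rule uniform, switches
i.i.d.), and a player whose switch probability is the choice model
evaluated at the block's rate and the previous feedback.  Defaults follow
the standard design: **80 trials per block**, ten blocks crossing the five
opponent rates {0.20, 0.35, 0.50, 0.65, 0.80} with the two roles in random
order (the three-rate set {0.25, 0.50, 0.75} is used for signal-analysis
sessions), fox/rabbit bookkeeping (fox wins on rule match), an independent
action-error process (default rate 0.05 — a typical error level for
speeded two-alternative rule selection), and lognormal response times
(median ≈ 570 ms) that play no causal role.  Variants: `mode="simple"`
(plain key choice, labels up/down, error process disabled),
`random_feedback=True` (outcomes replaced by a fair coin — the
non-competition control), and `error_rate_post_loss` (feedback-dependent
error rates, for constructed confounds).

Error trials keep the *intended* rule on record and switch indicators
derive from intended rules; `errors_corrupt_rule=True` instead records a
random rule on error trials (the executed response does not identify the
intention), which is the mechanism used to construct error-driven slope
artifacts in the noise-control tests.

`simulate_cohort` draws per-subject parameters from a Gaussian centred on
(ms, sm, pe, ss) = (0.48, −0.38, 0.21, 0.20) — the group-level estimates
for the standard rule-selection design — with between-subject SDs
(0.25, 0.20, 0.15, 0.15), chosen once as realistic individual variation
(large enough that some subjects show reversed biases, as observed
empirically, while keeping the population mean pattern).  Subject streams
are spawned independently from the master seed; identical seeds give
byte-identical logs.

`simulate_dyad` plays two model-governed players against each other in
real time; each player's `p_os` input is the running estimate of the
partner's actual switches, outcomes are strictly zero-sum, and no error
process is applied.  A memory-free (all-zero-parameter) player is
analytically unexploitable — any opponent wins exactly half the trials —
which the tests use as an oracle; exploitation is demonstrated against a
perseverating partner.

**Feedback-locked signals** (`simulate_neural_epochs`).  Epochs span
−200…+1050 ms around feedback onset on a fixed 10-ms grid (the analyses
are grid-agnostic; 10 ms keeps desk-scale runs light).  The signal is

```
baseline_wl(t) + gain · Σ_k β_k(wl, t) · x_k + subject offset + noise
```

with standardized context variables x_k ∈ {A: opponent overall switch
rate, B: opponent lag-1 switch, C: player lag-1 switch, A×B}.  Win-trial
coefficient curves are Gaussian bumps (peak 450 ms, width 150 ms,
amplitudes A 0.5, B 0.4, C 0.2, A×B −0.4 — signs mirroring the empirical
pattern); loss-trial curves are identical until 400 ms and then ramp
linearly to zero by 700 ms, emulating early activation followed by
suppression of context information after losses.  The ERP baseline adds a
feedback wave with an extra early negativity on losses (cosmetic: it is
absorbed by the intercept).  White Gaussian noise (SD 2.0) gives
single-subject coefficient SEs around 0.13 at ~230 trials per feedback
condition — informative but honestly noisy.  A per-subject multiplicative
gain (SD 0.1) creates individual differences; tying the gain to a
behavioural parameter constructs brain–behaviour correlations with known
ground truth.

What the generator deliberately does **not** emulate: within-session
learning or drift of the player's parameters, any RT–choice coupling,
opponents that adapt to the player, sensor geometry, artifacts,
autocorrelated (1/f) noise, or multi-channel structure.  Passing tests
therefore certify the estimators and the inferential logic under the
model's own assumptions — not robustness to real-data pathologies such as
non-stationarity or artifact contamination.

## Group-level inference

statsmodels provides no frequentist GLMM, so all multilevel *logistic*
analyses (history regressions, PPI step 2, per-time-point context
regressions) use the two-stage summary-statistics estimator that is
standard in single-trial cognitive-neuroscience analysis: per-subject ML
fits, then random-effects inference across subjects (mean, SE, t with
n−1 df; reported as z in the logistic tables).  This treats every
predictor's effect as random across subjects — the maximal structure — at
the cost of ignoring within-subject estimation noise, which is
conservative at these trial counts.  Subjects whose first-stage fit is
unstable (separation, |coef| > 50) are dropped with a notice and counted.

Linear mixed models (reversed-label slope contrast, stochasticity-vs-noise,
success regression) use statsmodels `MixedLM` with a stepwise fallback:
random intercept + slope → random intercept (REML, then ML), and — for the
paired two-rows-per-subject noise-control design, where the mixed model is
often singular — a within-subject fixed-effects OLS that gives the
equivalent conditional inference.  The final structure is always recorded
in the result.

Conventions fixed once and used throughout: continuous predictors are
z-scored and binary ones effect-coded (±1) within the fitted subset;
the opponent-rate regressor enters history models on the log-odds scale
(the generative model is exactly linear there, which makes the null-lag
calibration exact); post-loss label reversal negates the opponent-related
predictors (rate and opponent lags) and player-history predictors only
where the split models show an empirical sign flip; the signal analyses
reverse A and B by default and leave C unreversed (both variants
available).  Slopes for the behavioural contrast are least squares over
condition means on the proportion scale (a logistic-scale option exists).

**Dependent correlations.**  Post-win vs post-loss contrasts of
brain–behaviour correlations use Steiger's (1980) modified Dunn–Clark z
for dependent correlations sharing one variable, implemented directly and
validated by Monte-Carlo null calibration (the statistic is standard
normal under equality to within sampling error).

## Numerical choices and degenerate inputs

* Opponent rates must lie strictly inside (0, 1) wherever log-odds are
  taken; boundary values raise a domain error naming the value.  The
  opponent *simulator* accepts the closed interval (0 = never switch,
  1 = strict alternation).
* Running-average output clipped to [0.01, 0.99].
* Empty condition cells are omitted with a warning; grids with fewer than
  four distinct cells, single-rate designs, missing RT/error columns,
  all-identical parameter matrices and single-group success regressions
  raise explicit errors.
* PPI residuals with ~zero variance drop the interaction terms with a
  notice.  Residuals are z-scored within subject × feedback subsets, so
  recovered interaction signs are scale-free.
* Epoch grids must be strictly increasing with a fixed step; window
  averages use the half-open interval [lo, hi) and require at least one
  grid point.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script
(chosen as the package's standard working sizes): cohorts of 10–40
subjects × 10 blocks × 80 trials for behavioural analyses; 50 seeded
replicates for recovery, suppression-signature and calibration
experiments; 6–10 subjects × 6 blocks for signal cohorts; 199 bootstrap
resamples; 10⁴ random draws for algebraic identities and 10⁶ Bernoulli
draws for the simulation oracle.

## Known limitations

* The condition-average fit on a *heterogeneous* cohort estimates the
  parameters of the average curve, which is flatter than the curve of the
  average parameters (logistic averaging attenuation); cohort-level
  parameter recovery therefore uses per-subject fits.
* With a non-zero win-stay/lose-shift bias the post-win and post-loss
  switch-rate functions have slightly different *probability-scale* slopes
  even when `sm = 0`, because the logistic derivative depends on the
  intercept; exact slope symmetry holds at `ss = 0`.
* Two-stage logistic inference ignores first-stage uncertainty; with very
  few trials per subject its SEs can be optimistic.
* The trialwise fit conditions on the running-average `p_os` as if known;
  uncertainty in the opponent estimate is not propagated.
* `MixedLM` with very few groups (e.g. two experiments) estimates the
  grouping variance poorly; the fixed effects remain interpretable but the
  random-intercept variance should not be.
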