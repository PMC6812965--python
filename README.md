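# foxrabbit

Simulation and analysis of competitive choice in the **fox/rabbit game**, a
rule-selection variant of matching pennies.  On every trial two players each
choose one of two action rules; the *fox* wins when both pick the same rule,
the *rabbit* when they differ.  Because winning requires being unpredictable
while exploiting any regularity in the opponent, the game cleanly separates
two modes of action selection: **model-based** choice driven by a
representation of the opponent's switch tendency, and **memory-free,
stochastic** choice that ignores the context altogether.

The package is written for researchers in sequential decision making and
competitive games who want to (1) generate closed-loop synthetic game data
with known ground truth, (2) fit the feedback-contingent choice model that
separates model-based strength from low-level biases, and (3) run the
behavioural and single-trial signal analyses that test whether losses
temporarily suppress the internal model of the opponent.

## The choice model

The probability that a player switches away from the previously executed
rule is modelled as a logistic function of the opponent's switch rate
`p_os` (through its log-odds `os = ln(p_os / (1 − p_os))`) and the previous
trial's feedback `wl` (+1 win, −1 loss; action errors count as losses):

```
logit P(switch) = wl · os · (ms + sm · (1 − wl)/2) − pe − wl · ss
```

* `ms` — *model strength*: the post-win slope on `os`; `ms = 1` is exact
  probability matching of the opponent's switch rate.
* `sm` — *strategy mix*: the change of the model-based slope after losses
  (post-loss slope is `ms + sm` on the reversed-label axis); `sm ≈ −ms`
  means the model is completely suppressed after losses and choice becomes
  stochastic (switch rate ≈ 0.5 regardless of the opponent).
* `pe` — *perseveration*: an unconditional bias toward repeating the
  previous rule.
* `ss` — *win-stay/lose-shift*: a reinforcement bias that lowers the switch
  probability after wins and raises it after losses.

Two statsmodels-style estimators expose the model: `ConditionAverageModel`
(least squares on the mean switch rates over the opponent-rate ×
post-win/post-loss grid, residual-bootstrap CIs, R²) and `TrialwiseModel`
(Bernoulli maximum likelihood on a trial sequence; for human-vs-human dyads
the opponent rate input is a running within-block average of the partner's
observed switches).  Both return a `ChoiceModelResults` with estimates,
intervals, goodness of fit and a `summary()` table.

Around the model sit the study-style analyses: reversed-label slope
contrasts (post-loss opponent rates recoded `p → 1 − p` so slope magnitudes
are comparable), lag-1..3 history regressions, a stochasticity-vs-noise
control (does the slope contrast survive RT/error covariates?), success
regressions, and regression-based information analyses of feedback-locked
signals (per-time-point context coefficients, 300–700 ms window averages,
PPI of residual signal on upcoming choices, individual-difference
correlations with Steiger-z contrasts).

## Worked example

```python
import foxrabbit as fr

trials, subjects = fr.simulate_cohort(12, rng=1)       # 12 players x 10 blocks x 80 trials
grid = fr.condition_switch_rates(trials)               # (p_os, win/loss) cell means
res = fr.fit_condition_averages(grid)
print(res.summary())
```

```
Feedback-contingent choice model
  method:    condition_LS
  nobs:      10
  converged: True
  objective: 0.00140799
  R^2:       0.9723
 param   estimate       lo95       hi95
    ms     0.3008     0.2612     0.3449
    sm    -0.3496    -0.4083    -0.2941
    pe     0.1581     0.1261     0.1930
    ss     0.2034     0.1740     0.2315
```

The group-average fit recovers the signature pattern: a positive
model-strength `ms` with `sm < 0` of almost the same magnitude — after
losses the influence of the opponent model nearly vanishes — plus positive
perseveration and win-stay/lose-shift biases.  (The condition-average `ms`
is attenuated relative to the cohort's mean generating value of 0.48
because averaging heterogeneous logistic curves flattens them; the
per-subject trialwise fits recover the generating means.)  The reversed-label
slope contrast makes the suppression directly visible:

```python
slopes = fr.reversed_label_slopes(trials)
```

```
post-win slope  0.328
post-loss slope -0.055
interaction t = 5.98 (p = 9.2e-05)
```

A command-line interface mirrors the library
(`foxrabbit simulate/fit/analyze/neural/recover/report`); every run writes
a manifest with the seed and config needed to reproduce it.

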