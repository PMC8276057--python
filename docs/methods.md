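# Methods

## The task

The simulated environment is the simplified (single-choice) two-stage
Markov decision task. On each of 201 trials (three blocks of 67) the
agent picks one of two first-stage options. Option `a` leads to
second-stage state `a` with probability `p_common = 0.7` (the *common*
transition) and to the other state otherwise (*rare*). The second stage
pays a unit reward (a 5-cent coin in the human task) with a
state-specific probability that drifts across trials as a Gaussian
random walk, so there is always something left to learn. There is no
second-stage choice; the second stage is a pure outcome state.

Walk dynamics follow the convention established for this task family:
per-trial increments `N(0, 0.025^2)`, reflecting bounds at 0.25 and
0.75 (fold-back reflection `p -> 2*bound - p`, applied until inside the
bounds, implemented in closed form via the triangle-wave identity so
any excursion size is handled), and initial probabilities drawn
uniformly inside the bounds. All of these are `TaskConfig` fields, so a
study that uses different dynamics is one config edit away.

Orientation conventions (fixed once, used everywhere): trials, actions
and states are 0-based; action 0 = forest, state 0 = blue;
`majority_destination` is the identity map.

## The hybrid agent

Behaviour is generated (and fitted) by the standard hybrid of
model-free SARSA(λ) and model-based evaluation, adapted to the
one-choice variant:

    Q_MB(a) = p * V(major(a)) + (1 - p) * V(other(a))        p = p_common
    net(a)  = w * Q_MB(a) + (1 - w) * Q_MF(a) + persev * 1[a == prev]
    P(a)    = softmax(beta * net)(a)

and after observing (choice c, state s, reward r), with pre-update
values on the right-hand sides:

    d1 = V(s) - Q_MF(c)      Q_MF(c) += alpha * d1
    d2 = r - V(s)            Q_MF(c) += alpha * lam * d2
    V(s) += alpha * d2

Five free parameters: learning rate `alpha` in [0, 1], inverse
temperature `beta` in [0, 20] (0 = random responding, 20 =
near-deterministic), model-based weight `w` in [0, 1] (0 = habitual,
1 = goal-directed), eligibility trace `lam` in [0, 1] (how much of the
reward prediction error reaches the first-stage value directly), and
perseveration `persev` in [-1, 1] (stickiness of the previous choice).

Choices made here where the standard formulation leaves room:

- The perseveration bonus is added to `net` *before* multiplication by
  `beta`, so `beta = 0` silences it and produces exactly uniform
  choice. The repeat indicator is 0 on the first trial.
- `d2` uses the pre-update `V(s)`; the eligibility credit lands on
  `Q_MF(c)` before `V(s)` moves. The alternative ordering is
  observationally equivalent in this variant but the bookkeeping is
  fixed for reproducibility.
- Values initialise at 0.5 (the reward-range midpoint) to avoid a
  first-trial bias; exposed as `value_init`.
- The model-based system uses the *true* transition matrix (no
  transition learning), as in the standard hybrid model.
- With rewards in {0, 1} and values started inside [0, 1], all values
  remain in [0, 1] for any `alpha, lam` in [0, 1] (property-tested).

## Cohorts (the synthetic-data generator)

A cohort is defined by natural-scale parameter means plus a spread of
0.2 applied on the *unconstrained* scale (logit for unit-interval
parameters, scaled logit for `beta` and `persev`), then mapped back —
so every draw respects the parameter ranges, and "pure" cohorts with
`w` at a boundary stay essentially pure. Four canonical validation
cohorts ship with the package (`VALIDATION_COHORTS`): an empirical-means
hybrid (0.54, 5.24, 0.39, 0.57, 0.12), pure model-based (w = 1), pure
model-free (w = 0) and a balanced hybrid (w ≈ 0.5); cohort size
defaults to 100 agents, one 201-trial session each. Per-agent
simulation seeds derive as `seed + index`, so cohorts reproduce agent
by agent.

What the generator emulates: the study's generative structure —
session/block counts, 70/30 transitions, drifting Bernoulli rewards,
population heterogeneity of the five parameters. What it does not:
reaction times, fatigue or attention drift, block-break effects,
instruction (mis)understanding, and missed responses (a missed-response
code exists only in the empirical-log schema and the QC flagger).
Passing recovery and signature tests therefore validates the *pipeline*
(model, likelihood, sampler, regression) under the stated generative
assumptions, not the behaviour of human participants.

## Likelihood and per-subject estimation

The likelihood replays the observed sequence through the update rules
above and accumulates `ln P(choice_t | history)`. It is exactly
normalised: summed over all possible choice sequences for any fixed
outcome skeleton, the probability mass is 1 (tested exhaustively for
2- and 3-trial skeletons at 1e-9). The production implementation is a
numba-compiled loop vectorised over parameter vectors; an independent
pure-Python replay through the public agent functions is the
equivalence oracle in the tests.

Estimation runs on the unconstrained scale with independent standard
normal priors per coordinate (weakly informative and proper; the
original study's priors are not published, so recovered means —
especially the `w -> 0.22` shrinkage for pure model-free cohorts — are
prior-dependent to a degree). Two fitters:

- `fit_map`: multi-start L-BFGS on the log posterior (8 restarts drawn
  from the prior), used for quick point estimates and as an MCMC
  cross-check.
- `fit_mcmc` (the default for recovery): affine-invariant ensemble
  sampler, 16 walkers, 500 warmup + 1000 retained steps (16,000
  retained draws). Differential-evolution moves (80% DE, 20% snooker)
  are used instead of the default stretch move: on this posterior's
  correlated geometry they bring split-Rhat from ~1.2 to <1.05 and
  raise bulk ESS roughly four-fold at equal cost. Point estimates are
  marginal posterior medians mapped to the natural scale, per
  parameter. Split-Rhat (walkers as chains) >= 1.05 flags
  non-convergence without discarding output. Natural-scale boundary
  values are clamped by epsilon = 1e-6 before the logit; `beta` is
  capped at 20 by construction of its transform.

## Stay/switch analysis

Stay tables bin `stay(t) = 1[choice_t == choice_{t-1}]` by the previous
trial's transition and reward; empty cells are reported as undefined
(NaN), never zero. Opportunities span block boundaries by default (the
session is continuous); `exclude_block_starts` drops the first trial of
each block for sensitivity analyses.

The population-level signature test is the hierarchical logistic
regression

    stay ~ reward * transition + (1 + reward * transition | subject)

with independent subject-level random intercept and slopes. Predictor
coding is explicit and switchable — `effects` (+1 rewarded/common, -1
otherwise; the default) or `dummy` (0/1) — because coefficient
magnitudes are meaningless without it. Estimation is Bayesian MCMC:
adaptive Metropolis-within-Gibbs on the non-centred parameterisation
(subject blocks, then fixed effects, then log random-effect scales;
proposal scales adapted toward 35% acceptance during warmup), with
priors `Normal(0, 5)` on fixed effects and half-normal(1) on
random-effect SDs, 4 chains of 1500 warmup + 1500 retained sweeps.
Fixed-effect estimates are posterior means (conditional,
subject-specific scale), standard errors are posterior SDs, p-values
are two-sided normal. On identical synthetic data this matches lme4's
`glmer` point estimates to <0.01 and its Wald standard errors to a few
percent (the cross-check is part of the test suite); a mean-field
variational alternative was rejected because it underestimates
fixed-effect standard errors by about half.

One genuine subtlety: with `lam < 1`, *pure model-free* agents carry a
small real reward x transition interaction (the first-stage update
routes part of its credit through `V(state2)`, and which state was
visited depends on the transition). At 100 subjects x 200 stay
opportunities this effect (~0.03-0.04 effects-coded) sits near the
significance boundary; the model-free signature is therefore "reward
effect an order of magnitude larger than the interaction", not
"interaction exactly zero".

## Response-quality flagger

The online task warns participants who key-mash. The flagger computes
longest runs of identical key presses, strict key alternation, and
same-location choices, plus the maximum number of missed responses in
any 20-trial window; a run at or above threshold raises a flag and two
flagged patterns mark the session aborted (warn once, then stop). Keys
and locations are distinct streams: the simulator randomises option
screen-placement per trial, as the display does. Default thresholds
(13 consecutive, 13 alternating, 25 same-location, 5 missed in 20) were
set from run-length statistics so that an engaged hybrid learner
(stay probability ~0.65) false-flags in well under 5% of sessions —
with random key placement, P(a >= 13-run of same keys in 201 trials) ~
1%, and P(a >= 25-run of same locations at stay 0.7) ~ 1% — while a
single block of mechanical responding is always caught. All thresholds
are configurable.

## Recovery harness

`run_recovery` wires the stages together: sample cohort -> simulate
sessions -> fit each agent -> tabulate generating vs recovered means
(both the target means and the realised sampled means are recorded, so
either reading of "input" can be compared), with per-agent paired
records for correlations. Fit failures are counted and excluded from
means, never fatal. All seeds derive deterministically from one run
seed; identical inputs give byte-identical reports.

Problem sizes: the canonical validation run (and `scripts/acceptance.py`)
uses the full study conditions — 100 agents per cohort, 201 trials,
full-length chains. The test suite exercises the same pipeline at 25
agents per cohort, which preserves the cohort ordering of recovered
`w` (pure-MF < hybrid < pure-MB) and the recovery-error bounds at a
fraction of the cost; chain-length floors in the remaining tests were
chosen as the shortest runs whose diagnostics still pass.

## Known limitations

- Single-subject (non-hierarchical) fitting only, as in the study
  being validated; no group-level shrinkage, no model comparison.
- Recovered cohort means at the `w` boundaries carry prior-driven
  shrinkage (~0.2 toward mid-range) that depends on the unpublished
  original priors; mid-range cohorts recover within ~0.05.
- Perseveration is the least identifiable parameter at 201 trials; its
  recovered values scatter widely, consistent with the original
  validation's report.
- The random-walk parameters (sd, bounds, initialisation) are
  conventions, not published values; behavioural effect sizes (stay
  contrasts, regression coefficients) scale with them.
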