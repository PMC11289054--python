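# Methods

This note documents the models, estimation procedures, synthetic-data
assumptions and numerical choices behind the package. Everything stated
here is computed by the test suite or by `scripts/acceptance.py`; no
empirical claims beyond those computations are made.

## Task environments

**Two-armed bandit.** Four blocks of 40 trials alternate between gain
and loss framing (ABAB, random start). Each block introduces two fresh
stimulus pairs, interleaved in seeded random order, 20 presentations
each. Feedback is *congruent* with the pair's advantageous stimulus
with probability .8 (first pair) or .7 (second pair): under congruent
feedback the advantageous stimulus yields the good outcome (+1 in gain
blocks, 0 — an avoided loss — in loss blocks) and the other stimulus
the bad one (0 / −1); incongruent feedback swaps them. Drawing
congruency per trial makes the two options' outcomes anti-coupled
within a trial, which is the structure the double-update models
exploit.

**Reversal learning.** A single stimulus pair; three reward states
(.8/.2, .2/.8, .5/.5); rewards ±1. After each trial the state reverses
if the participant chose the most-rewarding option at least 7 times in
the last min(10, n) trials of the state, or after 16 trials. The
min(10, n) reading makes a reversal possible from trial 7 on; the
alternative (no reversal before 10 trials) is not distinguishable from
the published design description, and the hit-count reading is the one
consistent with "7 out of 10" as a count. In the 50/50 state the
most-rewarding option for the switch rule is the one that had
probability .2 in the preceding state. The first state is drawn
uniformly from the two asymmetric states; after a reversal the next
state is drawn uniformly from the other two (the design description
fixes neither; both are config-exposed). Sessions always run 250
trials.

Timeouts can be injected i.i.d. (default rate 0); timed-out trials
carry no reward and are skipped by all likelihoods, mirroring how
modelling handles them downstream.

## Model space

Six Rescorla–Wagner variants: {1, 2} learning rates × {chosen-only,
full double update, κ-weighted double update}. Q values start at 0 per
stimulus pair; bandit pairs are fresh per block (Q re-initialised),
the reversal task keeps one persistent pair across reversals. Choice is
logistic softmax in the Q difference with inverse temperature
τ ∈ [0, 20]. The published softmax omits the "1 +" in the denominator
(it would exceed 1); the standard logistic form is used.

Counterfactual recoding for double updating: bandit, block-wise —
r_chosen = 0 in a gain block → r_unchosen = +1; r_chosen = ±1 →
r_unchosen = 0; r_chosen = 0 in a loss block → r_unchosen = −1;
reversal task — r_unchosen = −r_chosen. The unchosen update is
κ·α_eff·δ_unchosen with κ = 1 for the full-DU variant.

Dual-rate gating is by prediction-error sign (α_gain when δ ≥ 0, ties
included), applied separately to the unchosen update via the sign of
δ_unchosen. The original description ("separate learning rates for
gains and losses") does not fix the rule; PE-sign gating is the only
one well defined in the loss block, where outcomes are {0, −1}. A
`gating="reward_sign"` switch implements the block-relative-valence
alternative.

Given rewards in {−1, 0, 1} and α, κ ∈ [0, 1], Q stays in [−1, 1]
(property-tested). Choice probabilities are floored at 1e−12 before
taking logs so the likelihood is finite at extreme τ.

## Estimation

**MLE.** Bounded L-BFGS-B from 20 uniform-random in-bounds starts
(seeded independently of data generation); lowest NLL wins, ties to the
first. BIC = k·ln(n_valid_trials) + 2·NLL per session; study tables sum
over participants.

**MAP.** Minimises NLL − Σ log Beta(θ; a, b) over unit-scale
parameters, τ on the τ/20 scale (no distribution family is published
for τ; beta on the rescaled axis matches the stated bounds and the beta
machinery of the other parameters). Bounds are kept 1e−6 inside the
unit interval where the beta log-density is finite. Uniform priors
reproduce MLE to 1e−3 (tested). Two prior sources exist:

* *population priors* — beta distributions moment-matched to the
  population moments. This is the default in simulated studies, where
  the generating distributions are the same distributions a T1 MAP
  analysis of the original data supplied; it reproduces the published
  simulated identifiability and retest rows.
* *empirical priors* — moment-matched to a cohort's own MLE estimates
  (`empirical_priors`), the only option for real data. A caveat
  documented here because it matters in practice: when a noisy
  parameter piles at its bound (τ at 20 is common at 160 trials), the
  matched beta becomes U-shaped (a, b < 1) and regularises *toward* the
  bounds; identifiability then barely improves on MLE. The study
  pipeline therefore defaults to population priors
  (`StudyConfig.map_prior = "population"`), and the empirical variant
  stays available as `map_prior = "empirical"`.

**Hierarchical Bayes.** Per parameter, participant unit-scale values
follow Beta(ωφ, (1−ω)φ) with group mean ω ~ U(0, 1) and precision
φ ~ U(2, 600); τ is modelled on the τ/20 scale and rescaled in
summaries. Point estimates are posterior means; DIC = mean deviance +
pD with pD = mean deviance − deviance at the posterior mean of the
participant-level parameters. The informed-prior mode for a second
session replaces the uniform prior on each ω with a beta matched to the
first session's ω posterior.

The sampler is an adaptive Metropolis-within-Gibbs scheme written for
this model's structure: (i) a joint random-walk proposal per
participant on the logit scale, accepted independently across
participants through a numba-compiled batched likelihood; (ii) cheap
centred random-walk updates of (ω, φ) touching only prior terms; and
(iii) an interweaved *non-centred* group move that proposes (ω, φ)
while holding every participant's beta quantile fixed, so the
participant cloud travels with the group distribution. The non-centred
move is what breaks the funnel coupling between precision and
participant spread; without it the precision chain can stall at large
values. Proposal scales adapt during warmup (Robbins–Monro toward
acceptance ~0.25–0.35) and freeze afterwards. Chains are initialised
from quick per-participant MLE fits plus jitter. Defaults: 4 chains,
1,000 warmup + 1,000 draws; split-R̂ and ESS (via arviz) are always
reported, and R̂ > 1.1 flags (not raises) the result.

**Joint two-session model.** Participant-level parameters are
logit-normal per session; for each model parameter the (T1, T2) pair on
the logit scale is bivariate normal with session means μ (Normal(0,
2.5²)), sds σ (Half-Normal(1.5)) and a free correlation ρ ~ U(−1, 1) —
the minimal structure that nests independence at ρ = 0
(`with_correlation=False` fixes ρ = 0 exactly). ρ's posterior mean is
the model-based reliability estimate. Sampling adds two ρ-specific
moves: an exact griddy-Gibbs draw of ρ from its one-dimensional
conditional on an atanh-spaced grid (dense near ±1), and a transport
move that changes ρ while preserving each participant's conditional T2
quantile. Participant proposals correlate the T1/T2 increments
according to the current ρ, since independent pair proposals are almost
surely rejected near ρ = 1.

Known limitation: with weakly identified parameters (α_gain, κ) and
small cohorts (n ≈ 30), the ρ posterior is close to flat — its
posterior mean is then an unstable summary, and the "all correlations
near 1 when T1 = T2 truly" benchmark is only approached (~.93–.96, not
> .98) even at n = 69. The dedicated acceptance test for that bound is
expected to fail and documents the gap honestly.

## Synthetic populations

The bandit population is beta by moment matching: τ mean 5.25, sd 2.18
on the /20 scale; α_gain mean .70, sd .23 (shapes 2.079, 0.891);
α_loss mean .25, sd .16 — the ground-truth moments of the published
simulated test–retest study. κ has no published moments; the package
default (mean .5, sd .2) is its own choice, picked once as a
mid-range, moderately dispersed value. No reversal-task population is
shipped, because no moments are published for it — callers must supply
one. A truncated-normal family switch exists for sensitivity checks.

Per-participant seeds derive from the master seed via
`SeedSequence(master, spawn_key=(stream, index))`, so enlarging a
cohort never reshuffles earlier participants, and identical configs are
byte-identical in output. The two sessions of a participant use
different streams (schedules re-randomised between sessions, which is
the natural reading of "two data sets per simulated participant").

What the generator does *not* emulate: response times, fatigue and
practice effects, attention lapses beyond i.i.d. timeouts,
task-schedule carry-over between sessions, or true parameter change
between sessions. Passing tests therefore show estimation-side
properties (identifiability ceilings, regularisation benefits,
attenuation of retest r below identifiability) — not that human
parameters are stable.

## Behavioural measures and exclusions

Accuracy excludes timed-out and 50/50-state trials; the advantageous
option in a loss block is the lower-loss-probability stimulus.
Feedback valence is block-relative in the bandit (an avoided loss, 0 in
a loss block, is positive feedback) and sign-based in the reversal
task. Win-stay/lose-shift transitions pair consecutive presentations of
the same stimulus pair (bandit) — "same stimulus" is undefined across
pairs — skipping pairs interrupted by a timeout; each presentation is
used at most once (count-reconciliation tested). Exclusions: timeout
fraction > 20% or accuracy < 55% at either session, invalid id (a
boolean stand-in for free-text misunderstanding checks), and
non-returners.

## Reliability statistics

Pearson r for reliability; ICC(3,1) (two-way mixed, consistency,
single measure) from the closed-form ANOVA decomposition for
agreement, verified against an independent ANOVA oracle and pingouin;
and a variance-components ICC from a REML mixed model with random
intercepts for participant and session (statsmodels MixedLM), reported
with the session and residual variance shares. With only two sessions
the session component is weakly identified: variances are bounded at
zero and boundary fits surface as zeros rather than being hidden.
Undefined measures propagate as NaN and drop pairwise.

## Problem sizes used in checks

The shipped checks run the simulated studies at n = 100 participants
(MAP/MLE; three seeds), n = 50–100 (hierarchical, 2 chains × 500
draws after 1,000 warmup), and n = 69 for the joint model (2 chains ×
1,000 draws after 2,000 warmup) — sizes chosen to match the original
study's cohorts while keeping a full run in the minutes range on one
CPU.
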