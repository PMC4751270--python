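# Methods

## The player model

One simulated participant plays two 50-round 2×2 games (PD and/or CG)
against a scripted confederate. The model carries four pieces of state
across rounds — declarative instance memory, a utility table, the two
trust accumulators, and a round clock — and all of it persists from
game 1 into game 2 with no gap: the between-game break (instructions,
surveys in the human procedure) is treated as a zero-duration clock
event. This persistence is the only channel through which anything can
transfer between games; there is no game identifier anywhere in the
model's representations, so transfer is carried entirely by learned
move contingencies, utilities, and accumulated trust.

Each round runs the pipeline:

1. **Predict.** Retrieve, among stored instances whose
   (own-previous, other-previous) slots exactly match the last round,
   the one with the highest noisy base-level activation
   `ln Σ_j (now − t_j)^(−d) + Logistic(0, s_act)`; its stored
   "other's current move" is the prediction. No match (round 1, novel
   situation, or everything below the retrieval threshold τ) yields
   *unknown*. Retrieval is single-chunk with exact cue matching — no
   blending, no partial matching.
2. **Choose.** The context is (prediction, own-previous,
   other-previous); the action with the larger utility plus
   `Logistic(0, s_util)` noise is played. An exact tie with zero noise
   is broken uniformly at random (this is the round-1 situation).
3. **Resolve.** The confederate's scripted move and the payoff matrix
   produce the round's point pair.
4. **Encode.** The triple (own-prev, other-prev, other-current) is
   (re-)presented in memory at the current tick (skipped on round 1,
   which has no previous moves).
5. **Update trust** from the move pair (see below), then **select the
   reward function** from the accumulator signs, compute the reward
   from this round's payoffs (with the other's previous payoff for the
   joint rule), and reinforce the chosen action:
   `U ← U + α (R − U)`. Only the action actually taken is credited.

`P2_prev` is 0 on the very first round of a session and carries the
last game-1 payoff into game-2 round 1 (continuous history).

The confederate resets at each game boundary (opening move, fresh
script version); it is a script, not a learner. Its strategy state is
always computed from the *actual* previous moves, including its own
forced moves.

## The trust mechanism

Directions are fixed by the mechanism: trust rises when the other
player cooperates (mutual cooperation, and the focal player's
unilateral defection), falls when the other defects (mutual defection,
unilateral cooperation); trust-invest rises under mutual defection and
falls after the focal player's exploited unilateral cooperation. Both
start at zero at the start of game 1 and are never reset. Alternation
rounds update through their constituent unilateral outcome (the
`alt_as_cooperation` option that treats a continued alternation as
cooperative evidence exists but is off everywhere).

Update *magnitudes* are a modelling choice, exposed on `ModelVariant`.
The plain mechanism (`TRUST_VARIANT`) uses symmetric unit steps. The
calibrated study configuration (`STUDY_TRUST_VARIANT`, the experiment
default) uses:

* `trust_weighting="loss-payoff"` — gains accrue in unit steps, losses
  are scaled by the magnitude of the focal payoff times
  `step_trust_down = 0.65`. Trust is slow to build and quick to
  destroy: a betrayal that costs 4 points (unilateral cooperation in
  PD) moves trust by −2.6, mutual defection in CG (−4 points each) by
  −2.6, mutual defection in PD (−1) by only −0.65, while every
  cooperative round adds +1. Two structural consequences matter:
  low-trustworthiness opponents tip the accumulator negative quickly
  and keep it there (mutual-defection spirals are corrosive,
  especially in CG), and sustained alternation — whose per-pair trust
  flow is +1 − 0.65 — remains mildly trust-positive, so the Chicken
  Game optimum does not undermine the trust that sustains it.
* `step_invest_down = 12` with unit upward steps — a failed repair
  attempt (cooperating and being defected on) sets the felt need to
  invest back by twelve mutual defections' worth of accumulation, so
  conciliatory probes are sparse rather than continual. Only the
  up/down *ratios* matter for behaviour, because reward-function
  selection depends on the accumulator signs alone.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `d` | memory decay exponent (–) | 0.5 | conventional base-level value |
| `s_act` | activation noise scale (–) | 0.25 | conventional retrieval noise |
| `tau` | retrieval threshold (activation units) | −10 | effectively disabled at session lags |
| `alpha` | utility learning rate (–) | 0.7 | see below |
| `s_util` | choice noise scale (utility units) | 0.2 | calibrated |
| `step_trust_down` | loss multiplier on trust (–) | 0.65 | calibrated |
| `step_invest_down` | invest setback per failed probe (–) | 12 | calibrated |
| `n_runs` / rounds / versions | experiment sizes | 50 / 50 / 10 | study design |

`alpha = 0.7` is well above the usual reinforcement-learning setting
for stationary tasks. It is load-bearing here: the trust mechanism
changes the reward function mid-game, and the utilities must
re-converge within a few rounds of each regime switch. With slow
learning, a conciliatory phase entered under the `P2` rule keeps
acting on utilities learned under `P1 − P2`; against Tit-for-Tat this
produces a cooperate/defect limit cycle that registers as spurious
alternation (~10% of low-trustworthiness second-game rounds, against
~1.7% in the published predictions). Fast re-valuation converts repair
attempts into either mutual cooperation or a quick return to mutual
defection, both of which match the published profiles.

## Calibration

The architecture parameters above are not published for this model, so
they were calibrated by grid search against three published 50-run
condition means, at the package's reference seed (11): first-game CG
alternation under T4T HT (31.5%), second-game CG alternation under T4T
LT (1.7%), and first-game PD mutual cooperation under T4T HT (49%).
The calibrated configuration reproduces all three within two standard
errors at n = 50 (28.8%, 1.68%, 52.2%), and the qualitative structure
holds at every seed tested: more alternation under HT than LT,
alternation falling from CG-played-first to CG-played-second,
PT4T-LT play dominated by mutual defection with persistent conciliatory
cooperation that the reactive variant lacks, and less mutual defection
than the reactive variant when the confederate switches strategy
mid-session.

Run-to-run variability is substantial and should be expected at other
seeds: individual runs are bistable (they either lock into the
cooperative/alternating regime or collapse into defection), so a
50-run condition mean is a mean over a bimodal distribution. Across
seeds the first-game PD HT mutual-cooperation mean, for example,
ranges over roughly 34–56%. The reference seed is part of the packaged
study configuration, exactly as the published predictions are one
realisation of their model's stochasticity.

Known quantitative departures from the published predictions, at any
calibration we explored: the model under-transfers alternation into a
second Chicken Game under HT (≈4–7% vs 21.2%), over-produces
first-game CG alternation under LT (≈15–20% vs 9.9%), and re-
establishes more mutual cooperation in a second PD under LT (≈26% vs
3%). All three trace to trust repair against Tit-for-Tat, which
reciprocates conciliation immediately; the published model evidently
kept its low-trust state more absorbing than this implementation does.

## Metrics layer

* **Outcome proportions.** Rounds are classified CC / CD / DC / DD /
  ALT from the focal player's perspective; ALT (opposite moves, both
  players switched from their own previous move) takes precedence over
  CD/DC so the five classes partition every round. Classification
  restarts at each game boundary (no cross-game alternation); profiles
  are indexed by a continuous 1–100 session round.
* **Repetition propensities** condition on the *four* move-pair
  outcomes of the previous round (the "A after AA" notation is
  move-pair based), within game, rounds ≥ 2; cells whose conditioning
  outcome did not occur are undefined (NaN) and excluded pairwise from
  difference summaries. Propensity differences are computed human −
  model: positive means the model under-predicted repetition.
* **Fit statistics** pool rounds × classes (× conditions for the
  overall figure) into one concatenated vector pair; Pearson *r* is
  flagged undefined on constant vectors. A per-outcome-averaged
  variant is provided as an option.
* **Transfer tests** are paired *t* over the 50 round-level proportion
  pairs, differenced first − second (negative *t* = more of the
  outcome when the game is played second), df = 49. Identical series
  give t = 0 by convention; a constant non-zero difference has no
  within-pair variance and reports ±∞.
* **Steiger's Z** for two dependent correlations sharing a variable
  uses Fisher z-transforms with the Dunn–Clark covariance term
  evaluated at the mean correlation.
* **Smoothing** (lowess, span 0.2, via statsmodels) is applied to
  plotted curves only, never to anything entering a statistic.

## Synthetic round logs

No human play records ship with the package, so the model–data
comparison pipeline is validated on synthetic logs whose ground truth
is known by construction: archetype runs (constant mutual cooperators
/ defectors, unilateral roles, perfect alternators) give exactly known
per-round class proportions, and i.i.d. move-pair mixtures give known
expected proportions. These fixtures exercise the full ingest →
classify → profile → compare path, but they are not behaviourally
human: real players produce serially correlated, non-stationary
sequences. Passing these tests therefore certifies the *metrics
arithmetic*, not the model's fit to people; the published human
comparisons (overall r = 0.66, RMSD = 0.19 and the variant ranking)
cannot be recomputed without the human round logs.

## Numerical and design choices

* One clock tick per round, continuous across games; activation is
  evaluated before the round's own encoding, so an instance first
  influences prediction one round after it is stored.
* Exact activation ties in retrieval and exact utility ties in choice
  are broken uniformly at random from the run's RNG stream.
* Randomness is split per (master seed, condition, run) into a
  version-assignment stream and a model-noise stream, so different
  model variants under one master seed face identical confederate
  scripts — variant comparisons are paired.
* Forced-round positions are drawn uniformly without replacement over
  all 50 rounds (the source design does not state any spacing
  constraint); the forcing *fraction* (10% / 35%) scales with the game
  length for non-standard round counts, with the standard counts 5
  and 17 at 50 rounds.
* Strategy opening moves are cooperate; Pavlov's "win" is a strictly
  positive previous payoff (payoffs are never zero in these games, so
  the boundary never binds).
* Payoffs are integers end to end; per-round optimal-stream means are
  exact rationals surfaced as floats.

## Limitations

The model is calibrated to, and validated against, its own published
simulation statistics — not against human data, which is not
deposited. The trust-step magnitudes and the loss-weighting scheme are
this package's modelling choices for quantities the source mechanism
leaves unspecified (directions only); alternative magnitude schemes
reproduce the qualitative structure but not the printed means. The
smoother is ordinary lowess rather than R's loess (tri-cube weighting
differences are cosmetic at span 0.2). The Pavlov strategy is
implemented and tested but not part of the 16-condition design.
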