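# trustgames

A computational cognitive model of **trust dynamics in iterated games
of strategic interaction**, together with the scripted confederate
agents, experiment harness, and analysis metrics needed to study it.

People playing the iterated Prisoner's Dilemma (PD) and Chicken Game
(CG) learn within a game (finding the game's optimal outcome — repeated
mutual cooperation in PD, asymmetric alternation in CG) and *between*
games (what happens in the first game shapes the second). The working
hypothesis embodied here is that the reciprocal trust players build or
destroy during play mediates these effects. The package implements a
learning agent that plays both games with no pre-programmed strategy,
driven by three mechanisms:

* **Instance-based sequence learning.** Each round the player stores
  the triple *(own previous move, other's previous move, other's
  current move)* in a declarative memory with power-law base-level
  activation, `A_i = ln Σ_j (t_now − t_j)^(−d) + ε`, and predicts the
  other player's next move by retrieving the most active matching
  instance.
* **Utility learning.** Actions are chosen by noisy utility
  maximisation per context (prediction × previous move pair), with
  difference learning `U ← U + α (R − U)` on the chosen action.
* **A two-accumulator trust mechanism** — the novel part. A *trust*
  accumulator tracks the other player's demonstrated trustworthiness;
  a *trust-invest* accumulator tracks the need to establish trust.
  Their signs select the reward function `R` that reinforces the
  round: `P1 + P2 − P2_prev` (joint improvement) when trust is
  positive, `P2` (conciliation) when only trust-invest is positive,
  `P1 − P2` (selfish) when both are at or below zero.

The opponent is a **scripted confederate**: Tit-for-Tat (T4T) or
Pavlov-Tit-for-Tat (PT4T, which exploits unilateral cooperation), with
trustworthiness manipulated by forced random cooperation (HT) or
defection (LT) on 10% (T4T) or 35% (PT4T) of rounds. The experiment
crosses game order (PDPD, PDCG, CGPD, CGCG) × strategy × trustworthiness
into 16 conditions, each simulated 50 times with persistent model state
across the two 50-round games.

The analysis layer computes round-by-round outcome proportions over
the five outcome classes (CC, CD, DC, DD, and alternation ALT),
round-by-round repetition propensities ("A after AA"), model–data
agreement (Pearson *r* and RMSD over paired profiles), paired *t*-tests
for transfer of learning, and Steiger's *Z* for comparing dependent
correlations.

## Worked example

```python
import trustgames as tg

# Simulate the CG-first Tit-for-Tat conditions (high vs low trustworthiness)
cfg = tg.ExperimentConfig()          # 50 runs, 2 x 50 rounds, reference seed 11
ht = tg.runs_to_frame(tg.run_condition(tg.get_condition(3), cfg))   # CGPD T4T HT
lt = tg.runs_to_frame(tg.run_condition(tg.get_condition(11), cfg))  # CGPD T4T LT

for name, frame, cid in [("HT", ht, 3), ("LT", lt, 11)]:
    alt = 100 * tg.game_outcome_series(frame, cid, 1, "ALT").mean()
    dd = 100 * tg.game_outcome_series(frame, cid, 1, "DD").mean()
    print(f"T4T {name}: first-game CG alternation {alt:.1f}%, mutual defection {dd:.1f}%")

prof = tg.proportion_profile(ht, 3)
print(prof.loc[[1, 25, 50]].round(2))
```

prints

```
T4T HT: first-game CG alternation 28.8%, mutual defection 30.4%
T4T LT: first-game CG alternation 19.6%, mutual defection 50.7%
                 CC   CD    DC    DD   ALT
session_round                             
1              0.52  0.0  0.48  0.00  0.00
25             0.22  0.0  0.12  0.34  0.32
50             0.12  0.0  0.06  0.40  0.42
```

Against a trustworthy T4T opponent the simulated players discover the
Chicken Game's optimal outcome — by round 50, 42% of runs are
alternating — while the untrustworthy opponent drives half of all
rounds into mutual defection. The profile table shows the transition:
round 1 is a coin-flip between cooperating and defecting, and
alternation (which needs two coordinated rounds) builds up over play.

The same experiment is available from the shell:

```bash
trustgames simulate --variant trust --conditions all --runs 50 --seed 11 --out runs.csv
trustgames metrics --in runs.csv --out profiles.csv
trustgames compare --model runs.csv --human human.csv --report fit.json
```

`compare` ingests any round log in the same CSV schema (one row per
player × game × round), so model predictions can be scored against
human or third-party play records with per-condition and overall
*r*/RMSD, and repetition-propensity differences.

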