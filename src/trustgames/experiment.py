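"""Experiment harness: the 16 conditions, round pipeline, and run logs.

A *condition* is a game order (PDPD, PDCG, CGPD, CGCG) crossed with the
confederate's strategy (T4T, PT4T) and trustworthiness (HT, LT) -- 16
cells. The simulated player runs each condition many times (50 by
default); within a run it plays two 50-round games, being assigned one
of the 10 confederate script versions per game uniformly at random.

Model state -- declarative memory, utilities, trust accumulators, and
the round clock -- persists from game 1 into game 2 with no gap, which
is what carries any transfer of learning between the games. The
confederate, by contrast, starts each game fresh from its opening move
(it is a script, not a learner).

Every round runs the pipeline: predict the other's move from memory,
choose by noisy utility, resolve payoffs against the scripted agent,
encode the new instance, update the trust accumulators, select the
reward function, and reinforce the chosen action.

Randomness is split into independent streams per (master seed,
condition, run): one for the version assignment and one for the
model's noise, so different model variants under one master seed face
identical confederate scripts -- enabling paired variant comparisons.
A ``strategy_switch`` flag makes the confederate swap T4T <-> PT4T at
game 2 (same trustworthiness), the probe for whether a model detects a
mid-session change of the other player's strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agents import (
    AgentScript,
    Strategy,
    Trustworthiness,
    agent_move,
    as_strategy,
    as_trust,
    generate_agent_versions,
)
from .cognition import (
    CognitiveParams,
    InstanceMemory,
    UtilityTable,
    choose_move,
    encode_instance,
    predict_other_move,
    update_utility,
)
from .games import GameSpec, Move, OutcomeClass, RoundRecord, classify_round, get_game
from .trust import (
    ModelVariant,
    RewardRule,
    STUDY_TRUST_VARIANT,
    TrustState,
    compute_reward,
    select_reward_rule,
    update_trust,
)


@dataclass(frozen=True)
class Condition:
    id: int
    game1: str
    game2: str
    strategy: Strategy
    trustworthiness: Trustworthiness

    @property
    def order(self) -> str:
        return f"{self.game1}{self.game2}"

    @property
    def label(self) -> str:
        return f"{self.order} {self.strategy.value} {self.trustworthiness.value}"


def _build_conditions() -> Tuple[Condition, ...]:
    orders = [("PD", "PD"), ("PD", "CG"), ("CG", "PD"), ("CG", "CG")]
    cells = [
        (Strategy.T4T, Trustworthiness.HT),
        (Strategy.PT4T, Trustworthiness.HT),
        (Strategy.T4T, Trustworthiness.LT),
        (Strategy.PT4T, Trustworthiness.LT),
    ]
    conds = []
    cid = 1
    for strat, tw in cells:
        for g1, g2 in orders:
            conds.append(Condition(cid, g1, g2, strat, tw))
            cid += 1
    return tuple(conds)


#: The 16 experimental conditions in canonical id order.
CONDITIONS: Tuple[Condition, ...] = _build_conditions()


def get_condition(cond_id: int) -> Condition:
    if not 1 <= cond_id <= len(CONDITIONS):
        raise ValueError(f"condition id must be 1..{len(CONDITIONS)}")
    return CONDITIONS[cond_id - 1]


def find_condition(order: str, strategy, trustworthiness) -> Condition:
    """Look up a condition by game order string and confederate cell."""
    strategy, trustworthiness = as_strategy(strategy), as_trust(trustworthiness)
    for c in CONDITIONS:
        if (c.order == order.upper() and c.strategy is strategy
                and c.trustworthiness is trustworthiness):
            return c
    raise ValueError(f"no condition {order} {strategy} {trustworthiness}")


@dataclass
class ExperimentConfig:
    """Knobs of the prediction experiment (defaults = study conditions)."""

    n_runs: int = 50
    rounds_per_game: int = 50
    n_versions: int = 10
    variant: ModelVariant = STUDY_TRUST_VARIANT
    params: CognitiveParams = field(default_factory=CognitiveParams)
    #: Reference seed of the packaged study; all reported statistics
    #: are reproducible from it.
    master_seed: int = 11
    strategy_switch: bool = False

    def __post_init__(self) -> None:
        if min(self.n_runs, self.rounds_per_game, self.n_versions) < 1:
            raise ValueError("counts must be positive")


@dataclass
class ModelState:
    """Everything the player carries across rounds (and across games)."""

    memory: InstanceMemory = field(default_factory=InstanceMemory)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    trust_state: TrustState = field(default_factory=TrustState)
    own_prev: Optional[Move] = None
    other_prev: Optional[Move] = None
    other_prev_payoff: Optional[float] = None  # P2 on the previous round


@dataclass
class AgentState:
    """The confederate's view of the last round (reset each game)."""

    own_prev: Optional[Move] = None
    other_prev: Optional[Move] = None
    own_prev_payoff: Optional[int] = None


@dataclass
class RoundOutcome:
    """A resolved round plus the model internals snapshotted after it."""

    record: RoundRecord
    trust: float
    invest: float
    reward_rule: RewardRule
    reward: float
    prediction: Optional[Move]


def play_round(
    state: ModelState,
    agent_state: AgentState,
    script: AgentScript,
    game: GameSpec,
    round_index: int,
    variant: ModelVariant,
    params: CognitiveParams,
    rng: np.random.Generator,
) -> RoundOutcome:
    """Run the full pipeline for one round; mutates both states."""
    state.memory.advance(1)

    prediction = predict_other_move(
        state.memory, state.own_prev, state.other_prev, params, rng)
    context = (prediction, state.own_prev, state.other_prev)
    move = choose_move(state.utilities, context, params, rng)
    other = agent_move(script, round_index, agent_state.own_prev,
                       agent_state.other_prev, agent_state.own_prev_payoff)
    record = RoundRecord.play(game, round_index, move, other)

    if state.own_prev is not None and state.other_prev is not None:
        encode_instance(state.memory, state.own_prev, state.other_prev, other)

    state.trust_state = update_trust(state.trust_state, move, other, variant,
                                     prev_focal=state.own_prev,
                                     prev_other=state.other_prev,
                                     focal_payoff=record.focal_payoff)
    rule = select_reward_rule(state.trust_state, variant)
    p2_prev = state.other_prev_payoff if state.other_prev_payoff is not None else 0.0
    reward = compute_reward(rule, record.focal_payoff, record.other_payoff, p2_prev)
    update_utility(state.utilities, context, move, reward, params)

    state.own_prev, state.other_prev = move, other
    state.other_prev_payoff = record.other_payoff
    agent_state.own_prev, agent_state.other_prev = other, move
    agent_state.own_prev_payoff = record.other_payoff

    return RoundOutcome(record, state.trust_state.trust,
                        state.trust_state.invest, rule, reward, prediction)


@dataclass
class GameLog:
    game_index: int
    game: str
    strategy: Strategy
    version_id: int
    rounds: List[RoundOutcome]


@dataclass
class RunLog:
    condition_id: int
    run_id: int
    variant_label: str
    games: List[GameLog]

    @property
    def n_rounds(self) -> int:
        return sum(len(g.rounds) for g in self.games)


class ScriptBank:
    """Lazy cache of the 10 script versions per strategy x trust cell."""

    def __init__(self, master_seed: int, n_versions: int, rounds: int):
        self.master_seed = master_seed
        self.n_versions = n_versions
        self.rounds = rounds
        self._cache: Dict[Tuple[Strategy, Trustworthiness], List[AgentScript]] = {}

    def get(self, strategy: Strategy,
            trust: Trustworthiness) -> List[AgentScript]:
        key = (strategy, trust)
        if key not in self._cache:
            # Stable per-cell sub-seed independent of conditions/variants.
            cell_index = list(Strategy).index(strategy) * 2 \
                + list(Trustworthiness).index(trust)
            seed = np.random.SeedSequence(
                [self.master_seed, 7919, cell_index]).generate_state(1)[0]
            self._cache[key] = generate_agent_versions(
                strategy, trust, self.n_versions, self.rounds, int(seed))
        return self._cache[key]


def _game_strategies(condition: Condition,
                     strategy_switch: bool) -> Tuple[Strategy, Strategy]:
    s1 = condition.strategy
    if not strategy_switch:
        return s1, s1
    s2 = Strategy.PT4T if s1 is Strategy.T4T else Strategy.T4T
    return s1, s2


def run_once(
    condition: Condition,
    run_id: int,
    config: ExperimentConfig,
    bank: ScriptBank,
) -> RunLog:
    """One simulated participant: two games with persistent model state."""
    assign_rng = np.random.default_rng(
        [config.master_seed, condition.id, run_id, 0])
    model_rng = np.random.default_rng(
        [config.master_seed, condition.id, run_id, 1])

    state = ModelState()
    strategies = _game_strategies(condition, config.strategy_switch)
    games = []
    for game_index, (game_name, strategy) in enumerate(
            zip((condition.game1, condition.game2), strategies), start=1):
        game = get_game(game_name)
        scripts = bank.get(strategy, condition.trustworthiness)
        script = scripts[int(assign_rng.integers(len(scripts)))]
        agent_state = AgentState()
        rounds = []
        for r in range(1, config.rounds_per_game + 1):
            rounds.append(play_round(state, agent_state, script, game, r,
                                     config.variant, config.params, model_rng))
        games.append(GameLog(game_index, game.name, strategy,
                             script.version_id, rounds))
    return RunLog(condition.id, run_id, config.variant.label, games)


def run_condition(condition: Condition, config: ExperimentConfig,
                  bank: Optional[ScriptBank] = None) -> List[RunLog]:
    """All runs of one condition (50 simulated participants by default)."""
    if bank is None:
        bank = ScriptBank(config.master_seed, config.n_versions,
                          config.rounds_per_game)
    return [run_once(condition, run_id, config, bank)
            for run_id in range(1, config.n_runs + 1)]


def run_experiment(config: ExperimentConfig,
                   conditions: Optional[Sequence[Condition]] = None
                   ) -> List[RunLog]:
    """Run every condition (or a subset) under one master seed."""
    if conditions is None:
        conditions = CONDITIONS
    bank = ScriptBank(config.master_seed, config.n_versions,
                      config.rounds_per_game)
    logs: List[RunLog] = []
    for condition in conditions:
        logs.extend(run_condition(condition, config, bank))
    return logs


def runs_to_frame(logs: Sequence[RunLog], player_type: str = "model",
                  include_state: bool = False) -> pd.DataFrame:
    """Flatten run logs to the canonical round-log table.

    Columns follow the round-log CSV schema; with ``include_state`` the
    per-round trust/invest accumulators, reward rule, and reward are
    appended (useful for diagnostics, not part of the schema).
    """
    rows = []
    for log in logs:
        for game_log in log.games:
            prev = None
            for outcome in game_log.rounds:
                rec = outcome.record
                cls = classify_round(prev, rec)
                row = {
                    "condition_id": log.condition_id,
                    "run_id": log.run_id,
                    "player_type": player_type,
                    "game_index": game_log.game_index,
                    "round": rec.round_index,
                    "focal_move": rec.focal_move.value,
                    "agent_move": rec.other_move.value,
                    "focal_payoff": rec.focal_payoff,
                    "agent_payoff": rec.other_payoff,
                    "outcome_class": cls.value,
                }
                if include_state:
                    row.update(game=game_log.game,
                               strategy=game_log.strategy.value,
                               version_id=game_log.version_id,
                               trust=outcome.trust, invest=outcome.invest,
                               reward_rule=outcome.reward_rule.value,
                               reward=outcome.reward)
                rows.append(row)
                prev = rec
    return pd.DataFrame(rows)
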