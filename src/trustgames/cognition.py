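"""Learning machinery of the player model: instance memory and utilities.

The player learns two things from the round stream:

* **Sequence prediction** (instance-based learning). After every round
  with history the model stores an *instance* -- the triple (own
  previous move, other's previous move, other's current move) -- in a
  declarative memory stamped with the current round tick. Re-encoding
  an existing triple appends a new presentation. To predict the other
  player's next move, the model retrieves, among instances whose
  (own_prev, other_prev) cues match the current situation exactly, the
  one with the highest noisy base-level activation

      A_i = ln( sum_j (now - t_j)^(-d) ) + eps,   eps ~ Logistic(0, s)

  and predicts that instance's stored "other's current move". More
  frequent and more recent experiences are therefore more likely to
  drive the prediction. If nothing matches (round 1, or a novel
  situation, or all activations below the retrieval threshold) the
  prediction is *unknown* (None).

* **Utility learning.** The model keeps a utility for each (context,
  action) pair, where the context is the predicted other move plus the
  previous move pair. Choices maximize utility plus logistic noise;
  after the round the chosen action's utility moves toward the reward
  by a fraction ``alpha`` (difference learning). Which reward arrives
  is decided by the trust mechanism (see :mod:`trustgames.trust`).

The clock ticks once per round and runs continuously across the two
games of a condition (the between-game break is a zero-duration event).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .games import Move

#: A prediction is a Move or None (unknown).
Prediction = Optional[Move]
#: Utility-table context: (predicted other move, own_prev, other_prev);
#: components are None on round 1 / unknown prediction.
Context = Tuple[Prediction, Optional[Move], Optional[Move]]
InstanceKey = Tuple[Move, Move, Move]


@dataclass
class CognitiveParams:
    """Architecture parameters of the learning machinery.

    d : base-level decay rate of declarative memory (dimensionless);
        0.5 is the conventional value.
    s_act : scale of the logistic activation noise.
    tau : retrieval threshold; -10 disables it for all practical lags.
    alpha : utility learning rate in (0, 1]. The default is high
        (0.7): because the trust mechanism switches the reward function
        mid-game, the player must re-value its actions within a few
        rounds of each regime change or it keeps acting on stale
        utilities. Calibrated against the published simulation
        statistics (see docs/methods.md).
    s_util : scale of the logistic utility (choice) noise.
    """

    d: float = 0.5
    s_act: float = 0.25
    tau: float = -10.0
    alpha: float = 0.7
    s_util: float = 0.2

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("decay d must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.s_act < 0 or self.s_util < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class Instance:
    """One declarative chunk with its presentation history."""

    own_prev: Move
    other_prev: Move
    other_cur: Move
    presentation_times: List[int] = field(default_factory=list)

    @property
    def key(self) -> InstanceKey:
        return (self.own_prev, self.other_prev, self.other_cur)


def activation(inst: Instance, now: int, params: CognitiveParams,
               noise: float = 0.0) -> float:
    """Base-level activation of *inst* at tick *now*, plus caller noise."""
    times = inst.presentation_times
    if not times:
        raise ValueError("instance has no presentations")
    if now <= max(times):
        raise ValueError(f"now={now} must exceed last presentation {max(times)}")
    base = math.log(sum((now - t) ** (-params.d) for t in times))
    return base + noise


@dataclass
class InstanceMemory:
    """Declarative memory over the (at most 8) move-triple instances."""

    instances: Dict[InstanceKey, Instance] = field(default_factory=dict)
    clock: int = 0

    def advance(self, ticks: int = 1) -> None:
        if ticks < 0:
            raise ValueError("clock cannot move backwards")
        self.clock += ticks

    def total_presentations(self) -> int:
        return sum(len(i.presentation_times) for i in self.instances.values())

    def to_json(self) -> str:
        payload = [
            {"own_prev": i.own_prev.value, "other_prev": i.other_prev.value,
             "other_cur": i.other_cur.value, "times": i.presentation_times}
            for i in self.instances.values()
        ]
        return json.dumps({"clock": self.clock, "instances": payload})


def encode_instance(memory: InstanceMemory, own_prev: Move,
                    other_prev: Move, other_cur: Move) -> InstanceMemory:
    """Store (or re-present) a move triple at the current clock tick."""
    key = (own_prev, other_prev, other_cur)
    inst = memory.instances.get(key)
    if inst is None:
        inst = Instance(own_prev, other_prev, other_cur)
        memory.instances[key] = inst
    if inst.presentation_times and memory.clock <= inst.presentation_times[-1]:
        raise ValueError("clock must advance between presentations")
    inst.presentation_times.append(memory.clock)
    return memory


def predict_other_move(
    memory: InstanceMemory,
    own_prev: Optional[Move],
    other_prev: Optional[Move],
    params: CognitiveParams,
    rng: np.random.Generator,
) -> Prediction:
    """Predict the other player's current move from matching instances.

    Retrieval is single-chunk with exact cue matching: only instances
    whose (own_prev, other_prev) slots equal the cues compete. Returns
    None when there are no cues (round 1), no match, or every noisy
    activation falls below the retrieval threshold.
    """
    if own_prev is None or other_prev is None:
        return None
    now = memory.clock
    best: Prediction = None
    best_act = -math.inf
    for inst in memory.instances.values():
        if inst.own_prev is not own_prev or inst.other_prev is not other_prev:
            continue
        noise = rng.logistic(0.0, params.s_act) if params.s_act > 0 else 0.0
        act = activation(inst, now, params, noise)
        if act > best_act or (act == best_act and rng.random() < 0.5):
            best_act = act
            best = inst.other_cur
    if best is None or best_act < params.tau:
        return None
    return best


@dataclass
class UtilityTable:
    """Learned utilities per (context, action); missing entries are 0."""

    utilities: Dict[Tuple[Context, Move], float] = field(default_factory=dict)

    def get(self, context: Context, action: Move) -> float:
        return self.utilities.get((context, action), 0.0)

    def to_json(self) -> str:
        payload = [
            {"context": [c.value if c is not None else None for c in ctx],
             "action": a.value, "utility": u}
            for (ctx, a), u in self.utilities.items()
        ]
        return json.dumps(payload)


def choose_move(
    table: UtilityTable,
    context: Context,
    params: CognitiveParams,
    rng: np.random.Generator,
) -> Move:
    """Pick the action with the highest noisy utility in *context*.

    With zero choice noise an exact tie is broken uniformly at random
    (the round-1 situation, where all utilities are still 0).
    """
    scores = {}
    for action in (Move.A, Move.B):
        noise = rng.logistic(0.0, params.s_util) if params.s_util > 0 else 0.0
        scores[action] = table.get(context, action) + noise
    if scores[Move.A] == scores[Move.B]:
        return Move.A if rng.random() < 0.5 else Move.B
    return max(scores, key=scores.get)


def update_utility(
    table: UtilityTable,
    context: Context,
    action: Move,
    reward: float,
    params: CognitiveParams,
) -> UtilityTable:
    """Difference learning: U <- U + alpha (reward - U) for the pair taken."""
    if not math.isfinite(reward):
        raise ValueError("reward must be finite")
    u = table.get(context, action)
    table.utilities[(context, action)] = u + params.alpha * (reward - u)
    return table
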