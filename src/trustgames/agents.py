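"""Scripted confederate agents: T4T, Pavlov, and PT4T with forced rounds.

The confederate plays one of three deterministic strategies:

* **T4T** (Tit-for-Tat): repeat the other player's previous move.
* **Pavlov** (win-stay / lose-shift): repeat its own previous move iff
  that move earned a positive payoff, otherwise switch.
* **PT4T** (Pavlov-Tit-for-Tat): T4T except that after its own winning
  defection (it defected, the other cooperated) it defects again
  (win-stay), so it never reciprocates unilateral cooperation. With the
  PD/CG payoffs this reduces to: cooperate only after mutual
  cooperation.

Trustworthiness is manipulated by *forced rounds*: on a pre-drawn set
of rounds the agent ignores its strategy and plays a fixed move --
cooperate (B) in the high-trustworthiness (HT) condition, defect (A)
in the low-trustworthiness (LT) condition. T4T agents have 5 forced
rounds out of 50 (10%); PT4T agents have 17 (35%), because PT4T is
inherently less trustworthy and needs a larger dose of cooperation to
raise its apparent trustworthiness. Ten script versions are generated
per strategy x trustworthiness cell; each simulated (or human) player
is assigned one version per game, which keeps the confederate's
"random" deviations identical across players given the same version.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .games import Move, as_move


class Strategy(str, enum.Enum):
    T4T = "T4T"
    PAVLOV = "PAVLOV"
    PT4T = "PT4T"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Trustworthiness(str, enum.Enum):
    HT = "HT"  # forced rounds cooperate
    LT = "LT"  # forced rounds defect

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def as_strategy(value) -> Strategy:
    if isinstance(value, Strategy):
        return value
    return Strategy(str(value).upper())


def as_trust(value) -> Trustworthiness:
    if isinstance(value, Trustworthiness):
        return value
    return Trustworthiness(str(value).upper())


#: Fraction of rounds that are forced (scripted random) per game.
#: T4T plays its strategy on 90% of rounds (5 forced out of 50); PT4T
#: on 65% (17 out of 50). Pavlov is not used in the scripted
#: experiment; it gets the T4T forcing level if scripted.
FORCED_FRACTION = {Strategy.T4T: 0.10, Strategy.PT4T: 0.35,
                   Strategy.PAVLOV: 0.10}


def forced_count(strategy, rounds: int = 50) -> int:
    """Number of forced rounds for a game of the given length."""
    return int(FORCED_FRACTION[as_strategy(strategy)] * rounds)


#: Forced-round counts at the standard 50-round game length.
FORCED_ROUNDS = {s: forced_count(s, 50) for s in Strategy}

#: Opening move for all strategies on round 1 (no history): cooperate.
OPENING_MOVE = Move.B


def strategy_move(
    strategy,
    own_prev: Optional[Move],
    other_prev: Optional[Move],
    own_prev_payoff: Optional[int],
) -> Move:
    """The strategy's move given last round's moves and its own payoff.

    All three history arguments are None together (round 1, returns the
    opening move) or present together.
    """
    strategy = as_strategy(strategy)
    history = (own_prev, other_prev, own_prev_payoff)
    if all(v is None for v in history):
        return OPENING_MOVE
    if any(v is None for v in history):
        raise ValueError("history arguments must be all None or all present")
    own_prev, other_prev = as_move(own_prev), as_move(other_prev)

    if strategy is Strategy.T4T:
        return other_prev
    if strategy is Strategy.PAVLOV:
        return own_prev if own_prev_payoff > 0 else own_prev.complement
    # PT4T: reciprocate CC and DD (as T4T), switch after own unilateral
    # cooperation, stay after own winning defection -> B only after CC.
    if own_prev is Move.B and other_prev is Move.B:
        return Move.B
    return Move.A


@dataclass(frozen=True)
class AgentScript:
    """A full 50-round confederate plan: strategy + forced-round schedule."""

    strategy: Strategy
    trustworthiness: Trustworthiness
    rounds: int
    forced_rounds: frozenset
    version_id: int
    seed: int

    @property
    def forced_move(self) -> Move:
        return Move.B if self.trustworthiness is Trustworthiness.HT else Move.A

    @property
    def n_strategy_rounds(self) -> int:
        return self.rounds - len(self.forced_rounds)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "trustworthiness": self.trustworthiness.value,
            "rounds": self.rounds,
            "forced_rounds": sorted(self.forced_rounds),
            "forced_move": self.forced_move.value,
            "version_id": self.version_id,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentScript":
        script = cls(
            strategy=as_strategy(d["strategy"]),
            trustworthiness=as_trust(d["trustworthiness"]),
            rounds=int(d["rounds"]),
            forced_rounds=frozenset(int(r) for r in d["forced_rounds"]),
            version_id=int(d["version_id"]),
            seed=int(d["seed"]),
        )
        if "forced_move" in d and as_move(d["forced_move"]) is not script.forced_move:
            raise ValueError("forced_move inconsistent with trustworthiness")
        return script


def generate_agent_versions(
    strategy,
    trust,
    n_versions: int = 10,
    rounds: int = 50,
    seed: int = 0,
    n_forced: Optional[int] = None,
) -> List[AgentScript]:
    """Generate the scripted versions for one strategy x trustworthiness cell.

    Forced-round positions are drawn uniformly without replacement from
    1..rounds, independently per version; the draw is deterministic
    given *seed*. Scripts are meant to be generated once per experiment
    and reused across runs and model variants.
    """
    strategy, trust = as_strategy(strategy), as_trust(trust)
    if n_versions < 1:
        raise ValueError("n_versions must be >= 1")
    k = forced_count(strategy, rounds) if n_forced is None else int(n_forced)
    if rounds < k:
        raise ValueError(f"rounds={rounds} < required forced count {k}")
    rng = np.random.default_rng(seed)
    scripts = []
    for version in range(1, n_versions + 1):
        forced = rng.choice(rounds, size=k, replace=False) + 1
        scripts.append(
            AgentScript(
                strategy=strategy,
                trustworthiness=trust,
                rounds=rounds,
                forced_rounds=frozenset(int(r) for r in forced),
                version_id=version,
                seed=int(seed),
            )
        )
    return scripts


def agent_move(
    script: AgentScript,
    round_index: int,
    own_prev: Optional[Move],
    other_prev: Optional[Move],
    own_prev_payoff: Optional[int],
) -> Move:
    """The confederate's move on *round_index* (1-based within its game).

    Forced rounds override the strategy; all other rounds follow
    strategy_move applied to the *actual* previous moves, including any
    forced move the agent itself played.
    """
    if not 1 <= round_index <= script.rounds:
        raise ValueError(
            f"round_index {round_index} out of range 1..{script.rounds}"
        )
    if round_index in script.forced_rounds:
        return script.forced_move
    return strategy_move(script.strategy, own_prev, other_prev, own_prev_payoff)


def scripts_to_yaml(scripts: Sequence[AgentScript]) -> str:
    return yaml.safe_dump([s.to_dict() for s in scripts], sort_keys=False)


def scripts_from_yaml(text: str) -> List[AgentScript]:
    return [AgentScript.from_dict(d) for d in yaml.safe_load(text)]


def scripts_to_json(scripts: Sequence[AgentScript]) -> str:
    return json.dumps([s.to_dict() for s in scripts], indent=2)


def scripts_from_json(text: str) -> List[AgentScript]:
    return [AgentScript.from_dict(d) for d in json.loads(text)]
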