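"""2x2 game definitions, round resolution, and outcome classification.

Two games are supported: the iterated Prisoner's Dilemma (PD) and the
iterated Chicken Game (CG). Both are symmetric 2x2 games with moves
A (defect) and B (cooperate). In PD the optimal iterated outcome is
repeated mutual cooperation (1 point per round each); in CG it is
asymmetric alternation of the unilateral-defection roles, which pays
(4 - 1) / 2 = 1.5 points per round on average to each player.

Rounds are classified into five outcome categories: mutual cooperation
(CC), unilateral cooperation (CD: focal cooperates, other defects),
unilateral defection (DC), mutual defection (DD), and asymmetric
alternation (ALT). A round is ALT when the players made opposite moves
on the current round and each made the opposite of their own previous
move -- the signature of the CG optimum. ALT takes precedence over
CD/DC so the five categories partition the rounds of a trajectory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Tuple


class Move(str, enum.Enum):
    """The two moves of a 2x2 game: A = defect, B = cooperate."""

    A = "A"
    B = "B"

    @property
    def complement(self) -> "Move":
        return Move.B if self is Move.A else Move.A

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def as_move(value) -> Move:
    """Coerce 'A'/'B' strings (or Move) to a Move."""
    if isinstance(value, Move):
        return value
    try:
        return Move(str(value))
    except ValueError as exc:
        raise ValueError(f"not a valid move: {value!r}") from exc


@dataclass(frozen=True)
class GameSpec:
    """A symmetric 2x2 game: name plus payoff map (focal, other) -> points."""

    name: str
    payoffs: Mapping[Tuple[Move, Move], Tuple[int, int]]

    def payoff(self, focal: Move, other: Move) -> Tuple[int, int]:
        return self.payoffs[(focal, other)]


_A, _B = Move.A, Move.B

#: Prisoner's Dilemma: mutual cooperation pays 1 each, mutual defection
#: costs 1 each, unilateral defection pays 4 to the defector and costs
#: the cooperator 4.
PD = GameSpec(
    "PD",
    {
        (_B, _B): (1, 1),
        (_A, _A): (-1, -1),
        (_A, _B): (4, -4),
        (_B, _A): (-4, 4),
    },
)

#: Chicken Game: mutual defection is the worst outcome (-4 each);
#: the unilateral cooperator loses only 1 while the defector earns 4.
CG = GameSpec(
    "CG",
    {
        (_B, _B): (1, 1),
        (_A, _A): (-4, -4),
        (_A, _B): (4, -1),
        (_B, _A): (-1, 4),
    },
)

GAMES: Mapping[str, GameSpec] = {"PD": PD, "CG": CG}


def get_game(name) -> GameSpec:
    """Look up a game by its canonical config token ("PD" or "CG")."""
    if isinstance(name, GameSpec):
        return name
    try:
        return GAMES[str(name).upper()]
    except KeyError as exc:
        raise ValueError(f"unknown game {name!r}; expected 'PD' or 'CG'") from exc


def payoff(game, focal: Move, other: Move) -> Tuple[int, int]:
    """Point pair (focal, other) for one resolved round of *game*."""
    return get_game(game).payoff(as_move(focal), as_move(other))


@dataclass(frozen=True)
class RoundRecord:
    """One resolved round, from the focal player's perspective."""

    round_index: int
    focal_move: Move
    other_move: Move
    focal_payoff: int
    other_payoff: int

    @classmethod
    def play(cls, game, round_index: int, focal: Move, other: Move) -> "RoundRecord":
        p_focal, p_other = payoff(game, focal, other)
        return cls(round_index, focal, other, p_focal, p_other)


class OutcomeClass(str, enum.Enum):
    CC = "CC"  # mutual cooperation
    CD = "CD"  # unilateral cooperation (focal B, other A)
    DC = "DC"  # unilateral defection (focal A, other B)
    DD = "DD"  # mutual defection
    ALT = "ALT"  # asymmetric alternation

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five classes in canonical presentation order.
OUTCOME_CLASSES = [c.value for c in (OutcomeClass.CC, OutcomeClass.CD,
                                     OutcomeClass.DC, OutcomeClass.DD,
                                     OutcomeClass.ALT)]

#: The four move-pair outcomes (no ALT), used for repetition propensities
#: and for the trust accumulators.
MOVE_PAIR_OUTCOMES = ["CC", "CD", "DC", "DD"]


def move_pair_outcome(focal: Move, other: Move) -> str:
    """4-way move-pair classification (CC/CD/DC/DD), focal perspective."""
    focal, other = as_move(focal), as_move(other)
    if focal is _B:
        return "CC" if other is _B else "CD"
    return "DC" if other is _B else "DD"


def classify_moves(
    prev: Optional[Tuple[Move, Move]], cur: Tuple[Move, Move]
) -> OutcomeClass:
    """Classify a round given (focal, other) move pairs.

    ALT requires a previous round on which each player made the
    complement of their current move; it never fires on round 1.
    """
    focal, other = as_move(cur[0]), as_move(cur[1])
    if focal is other:
        return OutcomeClass.CC if focal is _B else OutcomeClass.DD
    if prev is not None:
        pf, po = as_move(prev[0]), as_move(prev[1])
        if pf is focal.complement and po is other.complement:
            return OutcomeClass.ALT
    return OutcomeClass.CD if focal is _B else OutcomeClass.DC


def classify_round(prev: Optional[RoundRecord], cur: RoundRecord) -> OutcomeClass:
    """Classify a resolved round against its predecessor (None on round 1)."""
    prev_pair = None if prev is None else (prev.focal_move, prev.other_move)
    return classify_moves(prev_pair, (cur.focal_move, cur.other_move))


def optimal_stream_payoff(game, pattern: str, rounds: int) -> float:
    """Mean per-round payoff per player under a repeated optimal pattern.

    pattern "mutual_cooperation": both play B every round.
    pattern "alternation": the players swap unilateral-defection roles
    every round (requires an even number of rounds so each player holds
    each role equally often).
    """
    g = get_game(game)
    if rounds <= 0:
        raise ValueError("rounds must be positive")
    if pattern == "mutual_cooperation":
        return float(g.payoff(_B, _B)[0])
    if pattern == "alternation":
        if rounds % 2:
            raise ValueError("alternation requires an even number of rounds")
        mean = Fraction(g.payoff(_A, _B)[0] + g.payoff(_B, _A)[0], 2)
        return float(mean)
    raise ValueError(f"unknown pattern {pattern!r}")
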