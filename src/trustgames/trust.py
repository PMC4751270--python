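"""Two-accumulator trust mechanism and the switchable reward functions.

The player tracks the relationship with the other player through two
accumulators, both starting at zero at the start of the first game and
persisting across a condition's two games:

* **trust** -- the other player's demonstrated trustworthiness. It
  rises after outcomes where the other cooperated (mutual cooperation,
  and the focal player's unilateral defection) and falls after
  outcomes where the other defected (mutual defection, unilateral
  cooperation).
* **trust-invest** -- the felt need to *establish* trust. It rises
  after mutual defection and falls after unilateral cooperation
  (failed repair attempts), and is untouched by the other outcomes.

The accumulator signs select which reward function reinforces the
round's action:

=====================  =======================================
accumulator state      reward for the round
=====================  =======================================
trust > 0              joint payoff minus the other's previous
                       payoff (P1 + P2 - P2_prev)
trust <= 0, invest > 0 the other player's payoff (P2)
both <= 0              own minus other's payoff (P1 - P2)
=====================  =======================================

A *reactive* variant drops the invest accumulator (trust > 0 selects
the joint rule, otherwise the selfish rule); *fixed* variants pin one
of five reward functions for the whole session and never touch the
accumulators. Under sustained mutual defection the full mechanism
switches to rewarding the other's payoff -- occasional conciliatory
cooperation -- whereas the reactive variant stays selfish; that
divergence is the mechanism's signature.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

from .games import Move, as_move


class RewardRule(str, enum.Enum):
    """The five reward functions, named by their payoff arithmetic."""

    JOINT_MINUS_PREV = "P1+P2-P2prev"
    OTHER = "P2"
    SELFISH = "P1-P2"
    OWN = "P1"
    JOINT = "P1+P2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TrustState:
    trust: float = 0.0
    invest: float = 0.0


class VariantKind(str, enum.Enum):
    TRUST = "trust"
    REACTIVE = "reactive"
    FIXED = "fixed"


@dataclass(frozen=True)
class ModelVariant:
    """Which trust machinery a model run uses.

    TRUST: both accumulators, three reward rules. REACTIVE: trust
    accumulator only, two rules. FIXED: one pinned rule, accumulators
    inert. Step sizes are the per-event accumulator increments; the
    ``*_down`` steps apply to trust-decreasing / invest-decreasing
    events and default to the symmetric (upward) step. Negative events
    may be given more weight than positive ones (losses loom larger in
    trust formation), which is how the study configuration is
    calibrated -- see the experiment module.
    """

    kind: VariantKind = VariantKind.TRUST
    fixed_rule: Optional[RewardRule] = None
    step_trust: float = 1.0
    step_invest: float = 1.0
    step_trust_down: Optional[float] = None
    step_invest_down: Optional[float] = None
    #: Separate trust decrement for mutual defection; defaults to the
    #: general downward step. Weighting DD harder than unilateral
    #: cooperation makes sustained mutual defection corrosive while
    #: leaving coordinated alternation trust-neutral.
    step_trust_down_dd: Optional[float] = None
    #: How trust-update magnitudes are weighted. "unit": fixed steps.
    #: "payoff": every update scaled by the magnitude of the focal
    #: player's payoff that round (evidence counts for what it cost or
    #: earned). "loss-payoff": gains accrue in fixed unit steps but
    #: losses are payoff-scaled -- trust is slow to build and quick to
    #: destroy, and a costly betrayal (-4) hurts far more than a cheap
    #: one (-1). The calibrated study configuration uses "loss-payoff".
    trust_weighting: str = "unit"
    #: Treat an established-alternation round (opposite moves, both
    #: players switched) as cooperative evidence (+trust) rather than
    #: as its constituent unilateral outcome. Alternation is the
    #: coordinated optimum of the Chicken Game, so holding up one's end
    #: of it demonstrates trustworthiness the same way mutual
    #: cooperation does.
    alt_as_cooperation: bool = False

    def __post_init__(self) -> None:
        if self.kind is VariantKind.FIXED and self.fixed_rule is None:
            raise ValueError("FIXED variant requires a reward rule")
        if self.trust_weighting not in ("unit", "payoff", "loss-payoff"):
            raise ValueError(f"unknown trust weighting {self.trust_weighting!r}")

    @property
    def trust_down(self) -> float:
        return self.step_trust if self.step_trust_down is None \
            else self.step_trust_down

    @property
    def trust_down_dd(self) -> float:
        return self.trust_down if self.step_trust_down_dd is None \
            else self.step_trust_down_dd

    @property
    def invest_down(self) -> float:
        return self.step_invest if self.step_invest_down is None \
            else self.step_invest_down

    @property
    def label(self) -> str:
        if self.kind is VariantKind.FIXED:
            return f"fixed:{self.fixed_rule.value}"
        return self.kind.value

    @classmethod
    def parse(cls, token: str, calibrated: bool = True) -> "ModelVariant":
        """Parse a config token: trust | reactive | fixed:<rule>.

        With ``calibrated`` (the default) the trust/reactive tokens
        resolve to the calibrated study configuration; otherwise to the
        plain unit-step mechanism.
        """
        token = token.strip().lower()
        if token == "trust":
            return STUDY_TRUST_VARIANT if calibrated else cls(VariantKind.TRUST)
        if token == "reactive":
            return (STUDY_REACTIVE_VARIANT if calibrated
                    else cls(VariantKind.REACTIVE))
        if token.startswith("fixed:"):
            spec = token.split(":", 1)[1].upper().replace(" ", "")
            for rule in RewardRule:
                if rule.value.upper() == spec:
                    return cls(VariantKind.FIXED, fixed_rule=rule)
            raise ValueError(f"unknown reward rule in variant token {token!r}")
        raise ValueError(f"unknown model variant token {token!r}")


TRUST_VARIANT = ModelVariant(VariantKind.TRUST)
REACTIVE_VARIANT = ModelVariant(VariantKind.REACTIVE)

#: Calibrated study configuration of the trust mechanism: losses are
#: payoff-weighted (trust is slow to build, quick to destroy) with a
#: moderate extra down-weight, and a failed repair attempt sets the
#: invest accumulator back hard, so conciliatory probes are sparse.
#: These magnitudes were calibrated against the published simulation
#: statistics of the 16-condition experiment (see docs/methods.md);
#: the directions of all updates are fixed by the mechanism.
STUDY_TRUST_VARIANT = ModelVariant(
    VariantKind.TRUST,
    trust_weighting="loss-payoff",
    step_trust_down=0.65,
    step_invest_down=12.0,
)
STUDY_REACTIVE_VARIANT = ModelVariant(
    VariantKind.REACTIVE,
    trust_weighting="loss-payoff",
    step_trust_down=0.65,
)

#: All seven variants of the model-comparison protocol.
ALL_VARIANT_TOKENS = [
    "trust",
    "reactive",
    "fixed:P1",
    "fixed:P2",
    "fixed:P1+P2",
    "fixed:P1-P2",
    "fixed:P1+P2-P2prev",
]


def update_trust(state: TrustState, focal_move: Move, other_move: Move,
                 variant: ModelVariant = TRUST_VARIANT,
                 prev_focal: Optional[Move] = None,
                 prev_other: Optional[Move] = None,
                 focal_payoff: Optional[float] = None) -> TrustState:
    """Accumulator update for one resolved round (move-pair based).

    The update keys on the raw move pair, not the 5-way metrics
    classification: by default an alternation round moves the
    accumulators through its constituent unilateral outcome. With the
    variant's ``alt_as_cooperation`` flag set, a round that continues
    an established alternation (previous moves supplied, both players
    switched, opposite moves) counts as cooperative evidence instead.
    """
    if variant.kind is VariantKind.FIXED:
        return state
    focal_move, other_move = as_move(focal_move), as_move(other_move)
    trust, invest = state.trust, state.invest
    is_alt = (
        variant.alt_as_cooperation
        and prev_focal is not None and prev_other is not None
        and focal_move is not other_move
        and as_move(prev_focal) is focal_move.complement
        and as_move(prev_other) is other_move.complement
    )
    mode = variant.trust_weighting
    if mode == "unit":
        weight = 1.0
    else:
        if focal_payoff is None:
            raise ValueError(
                "payoff-weighted trust updates need the focal payoff")
        weight = abs(focal_payoff)
    if is_alt or other_move is Move.B:
        # Other cooperated (CC or focal unilateral defection), or the
        # pair is holding up a coordinated alternation.
        w = 1.0 if mode == "loss-payoff" else weight
        trust += w * variant.step_trust
    elif focal_move is Move.A:  # mutual defection
        trust -= weight * variant.trust_down_dd
    else:  # focal unilateral cooperation (exploited)
        trust -= weight * variant.trust_down
    if variant.kind is VariantKind.TRUST and not is_alt:
        if focal_move is Move.A and other_move is Move.A:  # mutual defection
            invest += variant.step_invest
        elif focal_move is Move.B and other_move is Move.A:  # unilateral coop
            invest -= variant.invest_down
    return replace(state, trust=trust, invest=invest)


def select_reward_rule(state: TrustState,
                       variant: ModelVariant = TRUST_VARIANT) -> RewardRule:
    """Reward function induced by the current accumulator signs."""
    if variant.kind is VariantKind.FIXED:
        return variant.fixed_rule
    if state.trust > 0:
        return RewardRule.JOINT_MINUS_PREV
    if variant.kind is VariantKind.TRUST and state.invest > 0:
        return RewardRule.OTHER
    return RewardRule.SELFISH


def compute_reward(rule: RewardRule, p1_n: float, p2_n: float,
                   p2_prev: Optional[float] = None) -> float:
    """Evaluate a reward rule on this round's payoffs.

    ``p2_prev`` is the other player's payoff on the previous round; the
    caller passes 0 on the very first round of a session and carries
    the game-1 final payoff into game 2 (continuous history).
    """
    if rule is RewardRule.JOINT_MINUS_PREV:
        if p2_prev is None:
            raise ValueError("P1+P2-P2prev requires the other's previous payoff")
        return float(p1_n + p2_n - p2_prev)
    if rule is RewardRule.OTHER:
        return float(p2_n)
    if rule is RewardRule.SELFISH:
        return float(p1_n - p2_n)
    if rule is RewardRule.OWN:
        return float(p1_n)
    if rule is RewardRule.JOINT:
        return float(p1_n + p2_n)
    raise ValueError(f"unknown reward rule {rule!r}")  # pragma: no cover
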