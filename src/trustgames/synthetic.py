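"""Synthetic round-log generator with controllable outcome mixes.

These builders produce tables in the canonical round-log schema whose
outcome composition is known by construction, so the metrics layer can
be validated against ground truth (and demonstrated without human
data). Two flavors:

* :func:`archetype_runs` -- each run follows a fixed behavioral
  archetype for the whole game (mutual cooperators, mutual defectors,
  unilateral roles, or perfect alternators), giving exactly known
  round-by-round class proportions.
* :func:`mixture_runs` -- each round's move pair is drawn i.i.d. from
  a given distribution over the four move pairs, giving known expected
  proportions with sampling noise.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .games import Move, payoff
from .io import validate_round_log

#: Archetype -> (focal, agent) move pattern per round (1-based).
_ARCHETYPES = {
    "CC": lambda r: ("B", "B"),
    "DD": lambda r: ("A", "A"),
    "CD": lambda r: ("B", "A"),
    "DC": lambda r: ("A", "B"),
    # Perfect asymmetric alternation: classified CD on round 1, ALT after.
    "ALT": lambda r: ("B", "A") if r % 2 else ("A", "B"),
}


def _rows_for_run(moves, game, condition_id, run_id, player_type,
                  game_index=1):
    rows = []
    for r, (f, a) in enumerate(moves, start=1):
        pf, pa = payoff(game, Move(f), Move(a))
        rows.append({
            "condition_id": condition_id,
            "run_id": run_id,
            "player_type": player_type,
            "game_index": game_index,
            "round": r,
            "focal_move": f,
            "agent_move": a,
            "focal_payoff": pf,
            "agent_payoff": pa,
        })
    return rows


def archetype_runs(
    composition: Dict[str, int],
    rounds: int = 50,
    game: str = "PD",
    condition_id: int = 1,
    player_type: str = "human",
    start_run_id: int = 1,
) -> pd.DataFrame:
    """Deterministic runs following fixed archetypes.

    ``composition`` maps archetype name (CC, CD, DC, DD, ALT) to the
    number of runs playing that pattern. From round 2 on, the class
    proportions equal the composition fractions exactly (ALT runs are
    CD on round 1).
    """
    unknown = set(composition) - set(_ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    rows = []
    run_id = start_run_id
    for name, count in composition.items():
        pattern = _ARCHETYPES[name]
        for _ in range(count):
            moves = [pattern(r) for r in range(1, rounds + 1)]
            rows.extend(_rows_for_run(moves, game, condition_id, run_id,
                                      player_type))
            run_id += 1
    return validate_round_log(pd.DataFrame(rows))


def mixture_runs(
    probs: Dict[str, float],
    n_runs: int,
    rounds: int = 50,
    game: str = "PD",
    condition_id: int = 1,
    player_type: str = "human",
    seed: int = 0,
) -> pd.DataFrame:
    """Runs whose move pairs are sampled i.i.d. per round.

    ``probs`` maps move-pair outcomes (CC, CD, DC, DD) to sampling
    probabilities (must sum to 1).
    """
    pairs = {"CC": ("B", "B"), "CD": ("B", "A"), "DC": ("A", "B"),
             "DD": ("A", "A")}
    names = list(probs)
    if set(names) - set(pairs):
        raise ValueError("probs keys must be move-pair outcomes CC/CD/DC/DD")
    p = np.asarray([probs[n] for n in names], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for run_id in range(1, n_runs + 1):
        draws = rng.choice(len(names), size=rounds, p=p)
        moves = [pairs[names[i]] for i in draws]
        rows.extend(_rows_for_run(moves, game, condition_id, run_id,
                                  player_type))
    return validate_round_log(pd.DataFrame(rows))


def two_game_archetype_runs(
    composition_game1: Dict[str, int],
    composition_game2: Dict[str, int],
    rounds: int = 50,
    games: Sequence[str] = ("PD", "CG"),
    condition_id: int = 1,
    player_type: str = "human",
) -> pd.DataFrame:
    """A full two-game session with per-game archetype compositions.

    Both compositions must describe the same number of runs; run k
    plays archetype compositions in listed order in both games.
    """
    n1 = sum(composition_game1.values())
    n2 = sum(composition_game2.values())
    if n1 != n2:
        raise ValueError("both games must cover the same number of runs")
    frames = []
    for game_index, (game, comp) in enumerate(
            zip(games, (composition_game1, composition_game2)), start=1):
        rows = []
        run_id = 1
        for name, count in comp.items():
            pattern = _ARCHETYPES[name]
            for _ in range(count):
                moves = [pattern(r) for r in range(1, rounds + 1)]
                rows.extend(_rows_for_run(moves, game, condition_id, run_id,
                                          player_type, game_index))
                run_id += 1
        frames.append(pd.DataFrame(rows))
    return validate_round_log(pd.concat(frames, ignore_index=True))
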