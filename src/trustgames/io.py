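"""Round-log CSV schema: the interchange format for play records.

One row per player x game x round, with columns:

    condition_id, run_id, player_type {model|human}, game_index {1,2},
    round (1-based within the game), focal_move {A,B}, agent_move
    {A,B}, focal_payoff, agent_payoff, outcome_class
    {CC,CD,DC,DD,ALT}

Simulated runs and ingested human (or third-party) records share this
schema, so the metrics layer treats them interchangeably. On read the
outcome_class column is recomputed from the moves if absent, and
validated if present.
"""

from __future__ import annotations

from typing import Union

import pandas as pd

from .games import OUTCOME_CLASSES, classify_moves

SCHEMA = [
    "condition_id",
    "run_id",
    "player_type",
    "game_index",
    "round",
    "focal_move",
    "agent_move",
    "focal_payoff",
    "agent_payoff",
    "outcome_class",
]

_INT_COLUMNS = ["condition_id", "run_id", "game_index", "round",
                "focal_payoff", "agent_payoff"]


def classify_frame(frame: pd.DataFrame) -> pd.Series:
    """Recompute the 5-way outcome class for every row of a round log."""
    sub = frame.sort_values(["condition_id", "run_id", "game_index", "round"])
    grp = sub.groupby(["condition_id", "run_id", "game_index"])
    prev_focal = grp["focal_move"].shift(1)
    prev_agent = grp["agent_move"].shift(1)
    labels = []
    for f, a, pf, pa in zip(sub["focal_move"], sub["agent_move"],
                            prev_focal, prev_agent):
        prev = None if pd.isna(pf) else (pf, pa)
        labels.append(classify_moves(prev, (f, a)).value)
    return pd.Series(labels, index=sub.index).reindex(frame.index)


def validate_round_log(frame: pd.DataFrame) -> pd.DataFrame:
    """Check schema and move/class domains; fill outcome_class if missing."""
    missing = [c for c in SCHEMA if c not in frame.columns and
               c != "outcome_class"]
    if missing:
        raise ValueError(f"round log missing columns: {missing}")
    frame = frame.copy()
    for col in ("focal_move", "agent_move"):
        bad = set(frame[col].unique()) - {"A", "B"}
        if bad:
            raise ValueError(f"invalid moves in {col}: {sorted(bad)}")
    if "outcome_class" not in frame.columns:
        frame["outcome_class"] = classify_frame(frame)
    else:
        bad = set(frame["outcome_class"].unique()) - set(OUTCOME_CLASSES)
        if bad:
            raise ValueError(f"invalid outcome classes: {sorted(bad)}")
    for col in _INT_COLUMNS:
        frame[col] = frame[col].astype(int)
    return frame


def write_round_log(frame: pd.DataFrame, path) -> None:
    """Write a round log to CSV in the canonical column order."""
    validate_round_log(frame)[SCHEMA].to_csv(path, index=False)


def read_round_log(path) -> pd.DataFrame:
    """Read and validate a round-log CSV."""
    return validate_round_log(pd.read_csv(path))
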