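"""Analysis layer: outcome proportions, propensities, and fit statistics.

All operations consume the canonical round-log table (one row per
player x game x round; see :mod:`trustgames.io` for the CSV schema),
which may hold either simulated runs or ingested human play records.

The two behavioral profiles are:

* **Round-by-round outcome proportions** -- for each round of the
  session, the fraction of runs (participants) whose round fell in
  each of the five outcome classes CC, CD, DC, DD, ALT. The five
  proportions partition each round.
* **Round-by-round repetition propensity** -- for each round N >= 2
  and each *previous* move-pair outcome (CC, CD, DC, DD), among the
  runs that experienced that outcome on round N - 1, the fraction that
  repeated their own move on round N ("A after AA" etc.). Cells whose
  conditioning outcome did not occur are undefined (NaN).

Model-human agreement is summarized by the Pearson correlation r and
the root mean squared deviation (RMSD) between paired proportion
profiles, pooled over rounds x classes (and over conditions for the
overall figure). Transfer of learning between games is tested with a
paired t-test across the 50 round-level proportions of a game played
first versus played second; dependent correlations (two models against
the same human data) are compared with Steiger's Z_H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .games import MOVE_PAIR_OUTCOMES, OUTCOME_CLASSES


def _rounds_per_game(frame: pd.DataFrame) -> int:
    return int(frame["round"].max())


def add_session_round(frame: pd.DataFrame) -> pd.DataFrame:
    """Append a continuous 1..100 session-round column across both games."""
    rpg = _rounds_per_game(frame)
    out = frame.copy()
    out["session_round"] = (out["game_index"] - 1) * rpg + out["round"]
    return out


def _select_condition(frame: pd.DataFrame,
                      condition_id: Optional[int]) -> pd.DataFrame:
    if condition_id is None:
        ids = frame["condition_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                "frame holds several conditions; pass condition_id")
        return frame
    sub = frame[frame["condition_id"] == condition_id]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition_id}")
    return sub


def proportion_profile(frame: pd.DataFrame,
                       condition_id: Optional[int] = None) -> pd.DataFrame:
    """Round-by-round proportion of each outcome class across runs.

    Returns a (session rounds) x (5 classes) table whose rows sum to 1.
    """
    sub = add_session_round(_select_condition(frame, condition_id))
    if sub.empty:
        raise ValueError("empty round log")
    counts = pd.crosstab(sub["session_round"], sub["outcome_class"])
    counts = counts.reindex(columns=OUTCOME_CLASSES, fill_value=0)
    prof = counts.div(counts.sum(axis=1), axis=0)
    prof.columns.name = None
    prof.index.name = "session_round"
    return prof


def repetition_propensity(frame: pd.DataFrame,
                          condition_id: Optional[int] = None) -> pd.DataFrame:
    """P(repeat own previous move) by round and previous move-pair outcome.

    Conditioning is on the 4-way move-pair outcome of the previous
    round within the same game (rounds >= 2 of each game). Undefined
    cells -- no run saw that outcome at that round -- are NaN.
    """
    sub = add_session_round(_select_condition(frame, condition_id))
    sub = sub.sort_values(["run_id", "game_index", "round"])
    grp = sub.groupby(["run_id", "game_index"])
    prev_focal = grp["focal_move"].shift(1)
    prev_agent = grp["agent_move"].shift(1)
    has_prev = prev_focal.notna()
    prev_outcome = pd.Series(
        np.where(prev_focal == "B",
                 np.where(prev_agent == "B", "CC", "CD"),
                 np.where(prev_agent == "B", "DC", "DD")),
        index=sub.index,
    )[has_prev]
    repeated = (sub["focal_move"] == prev_focal)[has_prev]
    table = (
        pd.DataFrame({
            "session_round": sub["session_round"][has_prev],
            "prev_outcome": prev_outcome,
            "repeated": repeated.astype(float),
        })
        .groupby(["session_round", "prev_outcome"])["repeated"]
        .mean()
        .unstack("prev_outcome")
        .reindex(columns=MOVE_PAIR_OUTCOMES)
    )
    table.columns.name = None
    table.index.name = "session_round"
    return table


def propensity_difference(human: pd.DataFrame,
                          model: pd.DataFrame) -> pd.DataFrame:
    """Elementwise human - model propensity difference.

    Positive cells mean the humans repeated more than the model
    predicted; a cell is NaN wherever either profile is undefined.
    """
    if human.shape != model.shape or list(human.columns) != list(model.columns):
        raise ValueError("propensity profiles are not congruent")
    if not human.index.equals(model.index):
        raise ValueError("propensity profiles cover different rounds")
    return human - model


@dataclass(frozen=True)
class FitResult:
    """Agreement between two paired proportion vectors."""

    r: float
    rmsd: float
    n: int

    @property
    def r_defined(self) -> bool:
        return math.isfinite(self.r)


def _flatten_pair(a: pd.DataFrame, b: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape:
        raise ValueError("profiles have different shapes")
    return a.to_numpy().ravel(), b.to_numpy().ravel()


def fit_statistics(a, b) -> FitResult:
    """Pearson r and RMSD between two matched profiles (or vector lists).

    Accepts two profile DataFrames, or two sequences of profile
    DataFrames (pooled into one concatenated vector pair, e.g. all 16
    conditions for the overall figure). r is NaN (flagged undefined)
    when either vector is constant.
    """
    if isinstance(a, pd.DataFrame):
        a, b = [a], [b]
    xs, ys = [], []
    for pa, pb in zip(a, b, strict=True):
        x, y = _flatten_pair(pa, pb)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return FitResult(r=r, rmsd=rmsd, n=int(x.size))


def fit_per_outcome_mean(a: pd.DataFrame, b: pd.DataFrame) -> FitResult:
    """Alternative per-condition summary: average the per-class r/RMSD."""
    rs, rmsds, n = [], [], 0
    for col in a.columns:
        res = fit_statistics(a[[col]], b[[col]])
        if res.r_defined:
            rs.append(res.r)
        rmsds.append(res.rmsd)
        n += res.n
    r = float(np.mean(rs)) if rs else float("nan")
    return FitResult(r=r, rmsd=float(np.mean(rmsds)), n=n)


def compare_frames(model: pd.DataFrame, human: pd.DataFrame,
                   per_outcome: bool = False) -> Dict:
    """Per-condition and pooled r/RMSD between two round-log tables."""
    shared = sorted(set(model["condition_id"]) & set(human["condition_id"]))
    if not shared:
        raise ValueError("no shared conditions between the two logs")
    per_condition: Dict[int, FitResult] = {}
    model_profiles, human_profiles = [], []
    for cid in shared:
        pm = proportion_profile(model, cid)
        ph = proportion_profile(human, cid)
        model_profiles.append(pm)
        human_profiles.append(ph)
        per_condition[cid] = (fit_per_outcome_mean(pm, ph) if per_outcome
                              else fit_statistics(pm, ph))
    overall = fit_statistics(model_profiles, human_profiles)
    return {"overall": overall, "per_condition": per_condition}


@dataclass(frozen=True)
class TransferResult:
    """Paired t-test of a game played first vs. played second."""

    t: float
    df: int
    p: float
    mean_first_pct: float
    sd_first_pct: float
    mean_second_pct: float
    sd_second_pct: float


def transfer_test(props_first: Sequence[float],
                  props_second: Sequence[float]) -> TransferResult:
    """Paired t over round-level proportions, differenced first - second.

    A significantly *negative* t (second > first) indicates transfer of
    learning into the second playing of the game. Means and SDs are
    reported as percentages.
    """
    x = np.asarray(props_first, dtype=float)
    y = np.asarray(props_second, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.ptp(d) < 1e-12:
        # Constant difference: zero yields t = 0, anything else has no
        # within-pair variance and the statistic diverges.
        zero = abs(d[0]) < 1e-12
        t = 0.0 if zero else math.copysign(math.inf, d[0])
        p = 1.0 if zero else 0.0
    else:
        res = stats.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
    return TransferResult(
        t=t,
        df=int(x.size - 1),
        p=p,
        mean_first_pct=float(100 * x.mean()),
        sd_first_pct=float(100 * x.std(ddof=1)),
        mean_second_pct=float(100 * y.mean()),
        sd_second_pct=float(100 * y.std(ddof=1)),
    )


def game_outcome_series(frame: pd.DataFrame, condition_id: int,
                        game_index: int, outcome: str) -> np.ndarray:
    """Round-level proportions of one outcome within one game of a condition."""
    prof = proportion_profile(frame, condition_id)
    rpg = _rounds_per_game(frame[frame["condition_id"] == condition_id])
    lo, hi = (game_index - 1) * rpg + 1, game_index * rpg
    return prof.loc[lo:hi, outcome].to_numpy()


def transfer_report(frame: pd.DataFrame) -> List[Dict]:
    """All game-played-first vs. played-second tests available in a log.

    For each game and each strategy x trustworthiness cell present, the
    game's optimal outcome (CC in PD, ALT in CG) is compared between
    the condition where that game came first and the one where it came
    second (mixed orders), with a paired t over the round-level
    proportions. Returns one record per feasible comparison.
    """
    from .experiment import CONDITIONS  # deferred: avoid import cycle

    by_key = {(c.order, c.strategy.value, c.trustworthiness.value): c
              for c in CONDITIONS}
    present = set(frame["condition_id"].unique())
    reports = []
    for strategy in ("T4T", "PT4T"):
        for trust in ("HT", "LT"):
            for game, other, outcome in (("PD", "CG", "CC"),
                                         ("CG", "PD", "ALT")):
                first = by_key.get((game + other, strategy, trust))
                second = by_key.get((other + game, strategy, trust))
                if first is None or second is None:
                    continue
                if first.id not in present or second.id not in present:
                    continue
                res = transfer_test(
                    game_outcome_series(frame, first.id, 1, outcome),
                    game_outcome_series(frame, second.id, 2, outcome))
                reports.append({
                    "game": game, "outcome": outcome,
                    "strategy": strategy, "trustworthiness": trust,
                    "first_condition": first.id,
                    "second_condition": second.id,
                    "t": res.t, "df": res.df, "p": res.p,
                    "mean_first_pct": res.mean_first_pct,
                    "mean_second_pct": res.mean_second_pct,
                })
    return reports


def steiger_z(r1: float, r2: float, r12: float, n: int) -> float:
    """Steiger's Z_H for two dependent correlations sharing one variable.

    r1 and r2 are the correlations of variables 1 and 2 with the shared
    variable (e.g. two models' predictions each correlated with the
    human data), r12 the correlation between variables 1 and 2, and n
    the number of paired observations. Uses Fisher z-transforms with
    the Dunn-Clark covariance term evaluated at the mean correlation.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    rbar = (r1 + r2) / 2.0
    rbar2 = rbar * rbar
    psi = r12 * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r12 * r12)
    c = psi / (1 - rbar2) ** 2
    return (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * c))


def smooth(series, span: float = 0.2) -> np.ndarray:
    """Local-linear (lowess) smoother for plotting round-by-round curves.

    NaN gaps are ignored when fitting and interpolated in the output.
    Purely presentational -- statistics are always computed on the raw
    series.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    y = np.asarray(series, dtype=float)
    x = np.arange(y.size, dtype=float)
    valid = np.isfinite(y)
    if valid.sum() < 2:
        return y.copy()
    return np.asarray(
        lowess(y[valid], x[valid], frac=span, it=0, xvals=x), dtype=float)
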