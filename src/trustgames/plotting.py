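"""Plot helpers for outcome-proportion and propensity profiles.

Thin matplotlib wrappers; every curve is smoothed with the lowess
smoother (span 0.2 by default) purely for readability, mirroring how
round-by-round profiles are usually rendered in this literature.
Requires the optional ``plot`` extra.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .metrics import smooth

_CLASS_COLORS = {"CC": "tab:green", "CD": "tab:orange", "DC": "tab:purple",
                 "DD": "tab:red", "ALT": "tab:blue"}


def plot_proportion_profile(profile: pd.DataFrame, ax=None,
                            span: float = 0.2, title: Optional[str] = None):
    """Plot the five smoothed outcome-proportion curves over the session."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for cls in profile.columns:
        ax.plot(profile.index, smooth(profile[cls].to_numpy(), span),
                label=cls, color=_CLASS_COLORS.get(cls))
    ax.set_xlabel("round")
    ax.set_ylabel("proportion of runs")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(ncol=5, fontsize=8)
    return ax


def plot_propensity_difference(diff: pd.DataFrame, ax=None,
                               span: float = 0.2,
                               title: Optional[str] = None):
    """Plot smoothed human-minus-model repetition-propensity differences."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for col in diff.columns:
        ax.plot(diff.index, smooth(diff[col].to_numpy(), span),
                label=f"repeat after {col}")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("round")
    ax.set_ylabel("human - model P(repeat)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
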