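"""Score-trajectory and loading plots for RM-ASCA+ results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .design import VISITS

__all__ = ["plot_scores", "plot_loadings"]


def plot_scores(results, envelope=None, component: int = 1, ax=None):
    """PC score trajectories over visits, one line per group level.

    If a bootstrap envelope is given, shaded 95% bands are drawn around each
    trajectory.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sl = results.scores_loadings
    col = f"PC{component}"
    frame = sl.scores_frame()
    if envelope is not None:
        frame = envelope.scores_frame()
    for level, sub in frame.groupby("level", sort=False):
        sub = sub.set_index("visit").reindex(list(VISITS))
        line, = ax.plot(list(VISITS), sub[col], marker="o", label=str(level))
        if envelope is not None:
            ax.fill_between(
                list(VISITS), sub[f"{col}_lo"], sub[f"{col}_hi"],
                alpha=0.15, color=line.get_color(),
            )
    evr = sl.explained_variance_ratio[component - 1]
    ax.set_xlabel("visit")
    ax.set_ylabel(f"{col} score ({100 * evr:.1f}%)")
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.legend(title=results.model.factor.name, fontsize=8)
    return ax


def plot_loadings(results, component: int = 1, envelope=None, ax=None, top: int | None = None):
    """Bar chart of one component's loadings, optionally with 95% CIs."""
    sl = results.scores_loadings
    col = f"PC{component}"
    frame = envelope.loadings_frame() if envelope is not None else sl.loadings_frame()
    if top is not None:
        frame = frame.reindex(frame[col].abs().sort_values(ascending=False).index[:top])
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.12 * len(frame)), 4))
    x = np.arange(len(frame))
    if envelope is not None:
        err = np.vstack([
            frame[col] - frame[f"{col}_lo"],
            frame[f"{col}_hi"] - frame[col],
        ])
        ax.bar(x, frame[col], yerr=np.abs(err), capsize=2)
    else:
        ax.bar(x, frame[col])
    ax.set_xticks(x)
    ax.set_xticklabels(frame["variable"], rotation=90, fontsize=6)
    ax.set_ylabel(f"{col} loading")
    ax.axhline(0.0, color="grey", lw=0.6)
    return ax
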