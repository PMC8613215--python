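"""Figure regeneration from trial tables and traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

COLORS = {"Left": "tab:blue", "Center": "tab:green", "Right": "tab:red"}


def condition_means_figure(table: pd.DataFrame, by_group: bool = True):
    """Mean +/- SD of the windowed force per condition (and group)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(table["group"].unique()) if by_group else ["all"]
    width = 0.8 / len(groups)
    for gi, grp in enumerate(groups):
        sub = table if grp == "all" else table[table["group"] == grp]
        stats = sub.groupby("condition")["mean_force_N"].agg(["mean", "std"])
        conds = [c for c in ("Left", "Center", "Right") if c in stats.index]
        x = np.arange(len(conds)) + gi * width
        ax.errorbar(
            x, stats.loc[conds, "mean"], yerr=stats.loc[conds, "std"],
            fmt="o", capsize=4, label=grp,
        )
        ax.set_xticks(np.arange(len(conds)) + width * (len(groups) - 1) / 2)
        ax.set_xticklabels(conds)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("windowed mean lateral force (N)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def force_profiles_figure(results_by_condition: dict):
    """Force-vs-time traces per condition (one TrialResult each)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, res in results_by_condition.items():
        ax.plot(res.time, res.force, color=COLORS.get(cond), label=cond)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("lateral force (N)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def sweep_figure(summary: pd.DataFrame):
    """Mean +/- SD force against kappa, per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, sub in summary.groupby("condition"):
        ax.errorbar(
            sub["kappa"], sub["mean_force_N"], yerr=sub["sd_force_N"],
            fmt="o-", capsize=4, color=COLORS.get(cond), label=cond,
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("causality parameter kappa")
    ax.set_ylabel("windowed mean lateral force (N)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
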