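"""Time-course figures: group mean +/- SEM differences and per-subject traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_group_timecourse(summary: pd.DataFrame, comparisons: pd.DataFrame,
                          path: str | Path, value_label: str = "GSH/Cr") -> None:
    """Mean difference vs baseline against scan midpoint, with significance."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    post = summary[summary.time_bin > 0]
    ax.errorbar(post.time_mean_min, post.mean_diff_vs_baseline,
                yerr=post.sem_diff, fmt="o-", capsize=3, color="k")
    ax.axhline(0.0, lw=0.8, color="grey")
    if comparisons is not None and not comparisons.empty:
        sig = comparisons.set_index("time_bin")["significant"]
        for _, row in post.iterrows():
            if sig.get(row.time_bin, False):
                ax.annotate("*", (row.time_mean_min,
                                  row.mean_diff_vs_baseline
                                  + (row.sem_diff or 0)),
                            ha="center", fontsize=14)
    ax.set_xlabel("time post dose (min)")
    ax.set_ylabel(f"Δ {value_label} vs baseline")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_subject_trajectories(table: pd.DataFrame, path: str | Path,
                              value: str = "gsh_cr",
                              value_label: str = "GSH/Cr") -> None:
    """Per-subject level versus time, one line per subject."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for sid, g in table[np.isfinite(table[value])].groupby("subject_id"):
        g = g.sort_values("time_min")
        ax.plot(g.time_min, g[value], "-o", ms=3, alpha=0.6, label=sid)
    ax.set_xlabel("time post dose (min)")
    ax.set_ylabel(value_label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
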