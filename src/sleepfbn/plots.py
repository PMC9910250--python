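"""Figures: electrode-layout network plots and group metric trajectories.

Networks are drawn with nodes at the eight 10–20 electrode positions and red
edges whose thickness is proportional to the connection weight (thicker =
stronger correlation).  Colors and layout are conventions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import METRIC_NAMES

#: Schematic 2-D scalp positions (x toward right ear, y toward nasion).
ELECTRODE_POSITIONS = {
    "C3": (-0.35, 0.05),
    "C4": (0.35, 0.05),
    "P3": (-0.35, -0.40),
    "P4": (0.35, -0.40),
    "P7": (-0.70, -0.45),
    "P8": (0.70, -0.45),
    "O1": (-0.25, -0.80),
    "O2": (0.25, -0.80),
}


def plot_network(weights, node_labels, ax=None, max_linewidth: float = 6.0):
    """Draw one weighted network on the electrode layout."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    weights = np.asarray(weights)
    n = len(node_labels)
    pos = {
        lab: ELECTRODE_POSITIONS.get(lab, (np.cos(2 * np.pi * k / n),
                                           np.sin(2 * np.pi * k / n)))
        for k, lab in enumerate(node_labels)
    }
    w_max = weights.max() or 1.0
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] <= 0:
                continue
            (x0, y0), (x1, y1) = pos[node_labels[i]], pos[node_labels[j]]
            ax.plot([x0, x1], [y0, y1], color="red", alpha=0.8,
                    linewidth=max_linewidth * weights[i, j] / w_max, zorder=1)
    for lab, (x, y) in pos.items():
        ax.scatter([x], [y], s=160, color="0.15", zorder=2)
        ax.annotate(lab, (x, y), color="white", ha="center", va="center", fontsize=6, zorder=3)
    ax.add_patch(plt.Circle((0, -0.35), 0.95, fill=False, color="0.6"))
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.4, 0.7)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_group_networks(group_nets: dict, node_labels, path) -> Path:
    """Grid of group-mean networks, one panel per (arm, timepoint)."""
    arms = sorted({arm for arm, _ in group_nets})
    tps = list(dict.fromkeys(tp for _, tp in group_nets))
    fig, axes = plt.subplots(len(arms), len(tps),
                             figsize=(3 * len(tps), 3 * len(arms)), squeeze=False)
    for r, arm in enumerate(arms):
        for c, tp in enumerate(tps):
            ax = axes[r][c]
            key = (arm, tp)
            if key in group_nets:
                plot_network(group_nets[key], node_labels, ax=ax)
            ax.set_title(f"{arm} / {tp}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_metric_trajectories(metrics_df, path, timepoints=None, metrics=METRIC_NAMES) -> Path:
    """Group mean ± SD of each metric across timepoints."""
    if timepoints is None:
        timepoints = list(dict.fromkeys(metrics_df["timepoint"]))
    fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3), squeeze=False)
    x = np.arange(len(timepoints))
    for k, metric in enumerate(metrics):
        ax = axes[0][k]
        for arm, style in (("treatment", "-o"), ("control", "--s")):
            sub = metrics_df[metrics_df["arm"] == arm]
            means = [sub.loc[sub["timepoint"] == tp, metric].mean() for tp in timepoints]
            sds = [sub.loc[sub["timepoint"] == tp, metric].std() for tp in timepoints]
            ax.errorbar(x, means, yerr=sds, fmt=style, capsize=3, label=arm)
        ax.set_xticks(x)
        ax.set_xticklabels(timepoints, fontsize=8)
        ax.set_title(metric)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
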