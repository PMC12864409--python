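"""Basic static figures: network graphs, centrality profiles, edge-CI and
stability plots.  All functions write a file and return the path; styling is
deliberately minimal."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clpn import CLPNNetwork
from .ggm import GGMNetwork


def _circle_layout(n: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n + np.pi / 2
    return np.c_[np.cos(ang), np.sin(ang)]


def plot_network(net: GGMNetwork, path: str | Path, *, max_width: float = 6.0) -> Path:
    """Undirected network: blue positive / red negative edges, width
    proportional to the absolute partial correlation."""
    pos = _circle_layout(len(net.node_labels))
    fig, ax = plt.subplots(figsize=(6, 6))
    wmax = max(np.abs(net.weights).max(), 1e-9)
    p = len(net.node_labels)
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if abs(w) < 1e-10:
                continue
            ax.plot(
                pos[[i, j], 0], pos[[i, j], 1],
                color="tab:blue" if w > 0 else "tab:red",
                linewidth=max_width * abs(w) / wmax, zorder=1,
            )
    ax.scatter(pos[:, 0], pos[:, 1], s=900, c="white", edgecolors="black", zorder=2)
    for lbl, (x, y) in zip(net.node_labels, pos):
        ax.annotate(lbl, (x, y), ha="center", va="center", zorder=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_centrality(tables: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Standardized strength/EI profiles, one line per wave."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 5), sharey=True)
    for ax, col, title in zip(
        axes, ["z_strength", "z_expected_influence"], ["Strength", "Expected influence"]
    ):
        for wave, tab in tables.items():
            ax.plot(tab[col], range(len(tab)), marker="o", label=wave)
        ax.set_yticks(range(len(next(iter(tables.values())))))
        ax.set_yticklabels(next(iter(tables.values()))["node"])
        ax.set_title(title)
        ax.axvline(0, color="grey", lw=0.5)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_edge_cis(table: pd.DataFrame, path: str | Path) -> Path:
    """Edges sorted by sample estimate with bootstrap interval bars."""
    tab = table.sort_values("estimate").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.18 * len(tab) + 1.5))
    y = np.arange(len(tab))
    ax.hlines(y, tab["ci_lower"], tab["ci_upper"], color="lightgrey")
    ax.plot(tab["boot_mean"], y, ".", color="black", ms=3, label="bootstrap mean")
    ax.plot(tab["estimate"], y, ".", color="tab:red", ms=3, label="sample")
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_yticks([])
    ax.set_xlabel("edge weight")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_stability(correlations: pd.DataFrame, path: str | Path) -> Path:
    """Mean and 95% band of subsample-vs-full centrality correlations."""
    g = correlations.groupby("drop")["correlation"]
    drops = sorted(correlations["drop"].unique())
    mean = g.mean().loc[drops]
    lo = g.quantile(0.025).loc[drops]
    hi = g.quantile(0.975).loc[drops]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(drops, lo, hi, alpha=0.3)
    ax.plot(drops, mean, marker="o")
    ax.axhline(0.7, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("proportion of cases dropped")
    ax.set_ylabel("correlation with full sample")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_clpn(model: CLPNNetwork, path: str | Path, *, max_width: float = 5.0) -> Path:
    """Directed lagged network; only reported cross-lagged edges are drawn."""
    pos = _circle_layout(len(model.node_labels))
    fig, ax = plt.subplots(figsize=(6, 6))
    p = len(model.node_labels)
    wmax = max(np.abs(model.W - np.diag(np.diag(model.W))).max(), 1e-9)
    for i in range(p):
        for j in range(p):
            w = model.W[i, j]
            if i == j or abs(w) <= model.report_threshold:
                continue
            ax.annotate(
                "", xy=pos[j], xytext=pos[i],
                arrowprops=dict(
                    arrowstyle="-|>",
                    color="tab:blue" if w > 0 else "tab:red",
                    lw=max_width * abs(w) / wmax,
                    shrinkA=18, shrinkB=18,
                ),
            )
    ax.scatter(pos[:, 0], pos[:, 1], s=900, c="white", edgecolors="black", zorder=2)
    for lbl, (x, y) in zip(model.node_labels, pos):
        ax.annotate(lbl, (x, y), ha="center", va="center", zorder=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
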