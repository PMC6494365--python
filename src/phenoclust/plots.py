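"""Diagnostic figures: consensus heatmap, consensus CDFs, PAC curve,
delta-area curve, per-cluster item-consensus box plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .consensus import ConsensusRun, ConsensusSweep
from .model_selection import PACProfile, consensus_cdf, delta_area
from .validity import UNASSIGNED, ItemConsensus

__all__ = [
    "plot_consensus_heatmap",
    "plot_consensus_cdfs",
    "plot_pac_curve",
    "plot_delta_area",
    "plot_item_consensus",
]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_consensus_heatmap(run: ConsensusRun, path: str | Path) -> Path:
    """Consensus matrix with patients ordered by final cluster — stable
    structure shows as a block-diagonal pattern."""
    order = np.argsort(run.final_labels, kind="stable")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(run.consensus[np.ix_(order, order)], vmin=0, vmax=1,
                   cmap="Blues", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="consensus")
    ax.set_title(f"Consensus matrix, k={run.k}")
    ax.set_xticks([])
    ax.set_yticks([])
    return _save(fig, path)


def plot_consensus_cdfs(sweep: ConsensusSweep, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    t = np.linspace(0, 1, 513)
    for k in sweep.ks:
        F = consensus_cdf(sweep.runs[k].consensus)
        ax.plot(t, F(t), label=f"k={k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_pac_curve(profile: PACProfile, path: str | Path) -> Path:
    ks = sorted(profile.pac_by_k)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(ks, [profile.pac_by_k[k] for k in ks], "o-")
    ax.axvline(profile.selected_k, color="grey", ls="--",
               label=f"selected k={profile.selected_k}")
    ax.set_xlabel("k")
    ax.set_ylabel(f"PAC {profile.interval}")
    ax.legend()
    return _save(fig, path)


def plot_delta_area(sweep: ConsensusSweep, path: str | Path) -> Path:
    da = delta_area(sweep)
    ks = sorted(da)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(ks, [da[k] for k in ks], "o-")
    ax.set_xlabel("k")
    ax.set_ylabel("relative change in CDF area")
    return _save(fig, path)


def plot_item_consensus(ic: ItemConsensus, path: str | Path) -> Path:
    labels = np.asarray(ic.labels)
    clusters = sorted(int(c) for c in np.unique(labels) if c != UNASSIGNED)
    data = [ic.values[labels == c] for c in clusters]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.boxplot(data, tick_labels=[str(c) for c in clusters])
    ax.set_xlabel("cluster")
    ax.set_ylabel("item consensus")
    ax.set_ylim(0, 1.02)
    return _save(fig, path)
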