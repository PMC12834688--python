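"""Optional figures mirroring the standard presentation of these analyses:
rarefaction curves, an UpSet-style media-overlap chart, and the pathway x
media heat map. Purely cosmetic; all numbers come from :mod:`actinonet.stats`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import RarefactionCurve

__all__ = ["plot_rarefaction", "plot_media_overlap", "plot_pathway_media"]


def plot_rarefaction(curves: Sequence[RarefactionCurve], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.plot(c.k, c.mean, label=c.stratum)
        ax.fill_between(c.k, c.mean - c.sd, c.mean + c.sd, alpha=0.2)
    ax.set_xlabel("strains accumulated")
    ax.set_ylabel("distinct items")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_media_overlap(exclusive: pd.DataFrame, set_sizes: pd.DataFrame, path: str | Path) -> Path:
    """Hand-rolled UpSet-style chart: intersection bars over a dot matrix,
    set-size bars on the left."""
    media = set_sizes["media"].tolist()
    combos = exclusive.sort_values(["n_media", "exclusive_count"], ascending=[True, False])
    fig, axes = plt.subplots(
        2, 2, figsize=(max(6, 0.45 * len(combos) + 2), 5),
        gridspec_kw={"height_ratios": [2, 1], "width_ratios": [1, 4]},
        sharex="col",
    )
    axes[0, 0].axis("off")
    bar_ax, size_ax, dot_ax = axes[0, 1], axes[1, 0], axes[1, 1]

    x = np.arange(len(combos))
    bar_ax.bar(x, combos["exclusive_count"], color="0.25")
    bar_ax.set_ylabel("exclusive count")

    size_ax.barh(np.arange(len(media)), set_sizes["set_size"], color="0.55")
    size_ax.set_yticks(np.arange(len(media)), media)
    size_ax.invert_xaxis()
    size_ax.set_xlabel("set size")

    for xi, combo in enumerate(combos["media_combination"]):
        members = set(combo.split("+"))
        for yi, m in enumerate(media):
            dot_ax.plot(xi, yi, "o", color="0.15" if m in members else "0.85", ms=6)
    dot_ax.set_yticks(np.arange(len(media)), media)
    dot_ax.set_xticks(x, ["" for _ in x])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_pathway_media(matrix: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(1 + 0.8 * matrix.shape[1], 1 + 0.5 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="fraction of pathway maximum")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
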