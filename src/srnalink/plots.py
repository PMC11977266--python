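"""Matplotlib figures: the concatenated-chromosome feature plot and the
TE family/class bar charts."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .intervals import natural_chrom_key

_TRACK_STYLE = {
    "DE gene": dict(color="darkblue", y=2),
    "DE TE Class I": dict(color="red", y=1),
    "DE TE Class II": dict(color="lightblue", y=0),
    "DE TE Unknown": dict(color="grey", y=0.5),
}


def chrom_plot(
    layout: pd.DataFrame, chrom_sizes: Mapping[str, int], path: str | Path
) -> None:
    """Feature tracks along the concatenated genome.

    DE genes (dark blue), Class I DE TE loci (red), Class II (light
    blue); genes in significantly enriched regions get orange diamonds.
    """
    fig, ax = plt.subplots(figsize=(14, 3.5))
    for track, sub in layout.groupby("track"):
        style = _TRACK_STYLE.get(track, dict(color="grey", y=0.5))
        ax.scatter(sub["cumulative_pos"], [style["y"]] * len(sub),
                   s=6, color=style["color"], label=track, alpha=0.6)
    sig = layout[layout["significant_region"]]
    if len(sig):
        ax.scatter(sig["cumulative_pos"], [2] * len(sig), s=60, marker="D",
                   facecolors="none", edgecolors="orange", linewidths=1.2,
                   label="significant region")
    acc = 0
    ticks, labels = [], []
    for chrom in sorted(chrom_sizes, key=natural_chrom_key):
        size = chrom_sizes[chrom]
        ax.axvline(acc, color="0.85", lw=0.5, zorder=0)
        ticks.append(acc + size / 2)
        labels.append(chrom)
        acc += size
    ax.set_xlim(0, acc)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_yticks([0, 1, 2])
    ax.set_yticklabels(["DE TE Class II", "DE TE Class I", "DE gene"], fontsize=8)
    ax.set_xlabel("genome position (chromosomes concatenated)")
    ax.legend(fontsize=7, loc="upper right", ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def count_barchart(
    counts: pd.DataFrame, label_col: str, path: str | Path, title: str = ""
) -> None:
    """Horizontal bar chart of a (label, count) table, largest on top."""
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.22 * len(counts) + 1)))
    if len(counts):
        sub = counts.iloc[::-1]
        ax.barh(sub[label_col].astype(str), sub["count"], color="steelblue")
    ax.set_xlabel("count")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
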