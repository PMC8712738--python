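"""Manhattan plots of the per-marker statistics with threshold lines."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _cumulative_positions(stats: pd.DataFrame):
    """Concatenate linkage groups on one axis; returns (x, tick_pos, labels)."""
    offset = 0
    x = np.empty(len(stats), dtype=float)
    ticks, labels = [], []
    for lg, idx in stats.groupby("linkage_group", sort=False).indices.items():
        pos = stats["position"].to_numpy()[idx]
        x[idx] = pos + offset
        ticks.append(offset + pos.max() / 2)
        labels.append(str(lg))
        offset += pos.max() + 1
    return x, ticks, labels


def manhattan(stats: pd.DataFrame, value_col: str, out_path: str | Path,
              lines: dict[str, float] | None = None,
              title: str = "") -> Path:
    """Genome-wide scatter of one statistic, one dot per marker.

    ``lines`` maps a label (e.g. "95%") to a y-value drawn as a horizontal
    threshold line.
    """
    out_path = Path(out_path)
    x, ticks, labels = _cumulative_positions(stats)
    y = stats[value_col].to_numpy()
    fig, ax = plt.subplots(figsize=(12, 3.2))
    lgs = stats["linkage_group"].to_numpy()
    palette = ("#4C72B0", "#AAAAAA")
    for i, lg in enumerate(dict.fromkeys(lgs)):
        m = lgs == lg
        ax.scatter(x[m], y[m], s=2, color=palette[i % 2], rasterized=True)
    for (label, val), color in zip((lines or {}).items(), ("blue", "red")):
        ax.axhline(val, color=color, lw=0.8, label=label)
    if lines:
        ax.legend(loc="upper right", fontsize=7)
    ax.set_xticks(ticks, labels, rotation=90, fontsize=6)
    ax.set_ylabel(value_col)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
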