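"""Treespace scatter plots (first two MDS axes)."""

from __future__ import annotations

from collections import Counter

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import ArgumentError
from .mds import Embedding

__all__ = ["plot_treespace"]

_PALETTE = ["#e377c2", "#4b0082", "#1f77b4", "#2ca02c", "#ff7f0e",
            "#8c564b", "#17becf", "#bcbd22", "#7f7f7f", "#d62728"]


def plot_treespace(embedding: Embedding, labels: list[str], out_path: str,
                   title: str = "Treespace (classical MDS of RF distances)",
                   color_map: dict[str, str] | None = None) -> str:
    """Scatter of MDS axes 1-2 with one colour per label value.

    ``labels`` gives one group label per point (a placement category or
    an analysis name); the legend lists each label with its point count.
    Empty groups never appear. Requires an embedding with k >= 2.
    """
    if embedding.k < 2:
        raise ArgumentError("plotting needs at least 2 MDS axes; rerun with mds_k >= 2")
    n = embedding.coordinates.shape[0]
    if len(labels) != n:
        raise ArgumentError(f"got {len(labels)} labels for {n} points")
    counts = Counter(labels)
    ordered = sorted(counts, key=lambda g: (-counts[g], g))
    fig, ax = plt.subplots(figsize=(7, 6))
    for i, group in enumerate(ordered):
        color = (color_map or {}).get(group, _PALETTE[i % len(_PALETTE)])
        xs = [embedding.coordinates[j, 0] for j in range(n) if labels[j] == group]
        ys = [embedding.coordinates[j, 1] for j in range(n) if labels[j] == group]
        ax.scatter(xs, ys, s=14, alpha=0.7, color=color,
                   label=f"{group} (n={counts[group]})", edgecolors="none")
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
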