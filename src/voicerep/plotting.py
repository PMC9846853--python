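"""Figure helpers: RDM heatmaps and MDS scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .rsa import RDM, percentile_transform


def plot_rdm(rdm: RDM, ax=None, percentile: bool = True):
    """Heatmap of an RDM, in display percentiles by default."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    shown = percentile_transform(rdm) if percentile and rdm.transform == "raw" else rdm
    im = ax.imshow(shown.matrix, cmap="viridis")
    ax.set_title(rdm.name or rdm.metric_tag)
    ax.set_xlabel("stimulus")
    ax.set_ylabel("stimulus")
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_mds(coords: pd.DataFrame, ax=None):
    """Scatter of RDM positions from :func:`voicerep.rsa.mds_embed` output
    (a frame with columns ``rdm``, ``x``, ``y``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords["x"], coords["y"])
    for _, row in coords.iterrows():
        ax.annotate(row["rdm"], (row["x"], row["y"]), fontsize=8)
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    return ax


def save_figure(ax, path: str | Path) -> None:
    ax.figure.savefig(str(path), bbox_inches="tight")
    plt.close(ax.figure)
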