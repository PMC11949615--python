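"""Basic plots: meta-identifiability heatmap, reconfiguration histograms,
additive explained-variance bars."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .connectivity import SEGMENTS

__all__ = ["plot_meta_identifiability", "plot_reconfiguration_histograms", "plot_additive_r2"]


def plot_meta_identifiability(meta, ax=None):
    """Heatmap of the 5 x 5 block meta-identifiability matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    stacked = meta.stacked()
    n = stacked.shape[0] // len(SEGMENTS)
    im = ax.imshow(stacked, cmap="viridis")
    for k in range(1, len(SEGMENTS)):
        ax.axhline(k * n - 0.5, color="w", lw=0.8)
        ax.axvline(k * n - 0.5, color="w", lw=0.8)
    ticks = [(i + 0.5) * n - 0.5 for i in range(len(SEGMENTS))]
    ax.set_xticks(ticks, SEGMENTS)
    ax.set_yticks(ticks, SEGMENTS)
    ax.figure.colorbar(im, ax=ax, label="correlation distance")
    return ax


def plot_reconfiguration_histograms(vectors: dict, axes=None):
    """Side-by-side histograms of per-transition reconfiguration values."""
    names = list(vectors)
    if axes is None:
        _, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        v = vectors[name].values
        ax.hist(v, bins=15, color="steelblue", edgecolor="k")
        ax.axvline(v.mean(), color="crimson", ls="--")
        ax.set_title(f"{name} (mean {v.mean():.3f})")
        ax.set_xlabel("correlation distance")
    return axes


def plot_additive_r2(result, ax=None):
    """Cumulative explained variance as predictors enter in order."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.bar(range(len(result.additive_r2)), result.additive_r2, color="gray")
    ax.set_xticks(range(len(result.predictor_order)), result.predictor_order, rotation=45)
    ax.set_ylabel("cumulative $R^2$")
    ax.set_ylim(0, 1)
    return ax
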