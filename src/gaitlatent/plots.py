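"""Plotting helpers: VAF curves, variance-ratio stacks, latent scatters."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_vaf_curves(vaf_by_reducer: dict[str, list[float]], ax=None):
    """VAF (%) versus latent width for each reducer."""
    if ax is None:
        _, ax = plt.subplots()
    for name, values in vaf_by_reducer.items():
        ax.plot(range(1, len(values) + 1), values, marker="o", label=name)
    ax.set_xlabel("latent dimensions")
    ax.set_ylabel("VAF (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax


def plot_variance_ratios(ratios_by_width: dict[int, np.ndarray], ax=None):
    """Stacked per-dimension variance ratios across bottleneck widths."""
    if ax is None:
        _, ax = plt.subplots()
    widths = sorted(ratios_by_width)
    bottoms = np.zeros(len(widths))
    max_dims = max(len(ratios_by_width[w]) for w in widths)
    for dim in range(max_dims):
        heights = [
            ratios_by_width[w][dim] if dim < len(ratios_by_width[w]) else 0.0
            for w in widths
        ]
        ax.bar(widths, heights, bottom=bottoms, width=0.7,
               color="tab:blue" if dim == 0 else None)
        bottoms += np.asarray(heights)
    ax.set_xlabel("bottleneck width")
    ax.set_ylabel("variance ratio")
    return ax


def plot_latent_scatter(latent: np.ndarray, labels, ax=None, title: str = ""):
    """2-D latent points colored by class or subject label."""
    if ax is None:
        _, ax = plt.subplots()
    labels = np.asarray(labels)
    for value in np.unique(labels):
        mask = labels == value
        ax.scatter(latent[mask, 0], latent[mask, 1], s=4, label=str(value))
    ax.set_xlabel("latent 1")
    ax.set_ylabel("latent 2")
    if title:
        ax.set_title(title)
    ax.legend(markerscale=3, fontsize="small")
    return ax
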