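"""Plotting helpers for fitted gradient results."""
from __future__ import annotations

import numpy as np

__all__ = ["plot_variance_explained", "plot_gradient_scatter", "plot_subdivision_boxes"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_variance_explained(results, ax=None, n_show: int = 40):
    """Bar plot of the variance-explained spectrum."""
    ax = _ax(ax)
    share = results.variance_explained[:n_show]
    ax.bar(np.arange(1, share.size + 1), 100 * share, color="0.3")
    ax.set_xlabel("gradient")
    ax.set_ylabel("variance explained (%)")
    return ax


def plot_gradient_scatter(results, gx: int = 1, gy: int = 2, ax=None):
    """Scatter of seed voxels in the plane of two gradients, colored by the
    first of them."""
    ax = _ax(ax)
    x = results.gradients.gradient(gx)
    y = results.gradients.gradient(gy)
    ax.scatter(x, y, c=x, cmap="viridis", s=12)
    ax.set_xlabel(f"gradient {gx}")
    ax.set_ylabel(f"gradient {gy}")
    return ax


def plot_subdivision_boxes(profiles, gradient: int = 1, ax=None):
    """Median-ordered box plots of gradient values per functional subdivision."""
    ax = _ax(ax)
    sub = profiles[profiles["gradient"] == gradient]
    order = sub.drop_duplicates("network").sort_values("median")["network"]
    data = [sub.loc[sub["network"] == n, "value"].to_numpy() for n in order]
    ax.boxplot(data, tick_labels=list(order))
    ax.set_ylabel(f"gradient {gradient} value")
    ax.tick_params(axis="x", rotation=45)
    return ax
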