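"""Basic plot helpers: consensus/kernel heatmaps and weight boxplots."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_kernel_heatmap", "plot_weight_boxplot"]


def plot_kernel_heatmap(values: np.ndarray, labels: np.ndarray | None = None,
                        ax=None, cmap: str = "Blues"):
    """Heatmap of a similarity matrix, optionally sorted by cluster labels."""
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if labels is not None:
        order = np.argsort(np.asarray(labels), kind="stable")
        values = values[np.ix_(order, order)]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(values, cmap=cmap, vmin=0.0, vmax=max(1.0, values.max()))
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    ax.set_xlabel("observation")
    ax.set_ylabel("observation")
    return ax


def plot_weight_boxplot(weights: np.ndarray, dataset_names=None, ax=None):
    """Boxplot of per-observation kernel weights, one box per dataset."""
    import matplotlib.pyplot as plt

    weights = np.asarray(weights, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    names = dataset_names or [f"dataset {m + 1}" for m in range(weights.shape[1])]
    ax.boxplot([weights[:, m] for m in range(weights.shape[1])], tick_labels=list(names))
    ax.set_ylabel("kernel weight")
    return ax
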