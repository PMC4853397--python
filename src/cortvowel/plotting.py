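"""Small matplotlib helpers for reports (output-ratio bars, weight maps, CC matrices)."""

from __future__ import annotations

import numpy as np


def plot_confusion_ratios(confusion, classes, ax=None):
    """Grouped bars of classification output ratios per true task."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    confusion = np.asarray(confusion)
    n = len(classes)
    x = np.arange(n)
    width = 0.8 / n
    for j, cls in enumerate(classes):
        ax.bar(x + j * width, confusion[:, j], width, label=f"-> {cls}")
    ax.axhline(1 / n, ls=":", color="k", lw=0.8)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(classes)
    ax.set_xlabel("true task")
    ax.set_ylabel("output ratio")
    ax.legend(fontsize=8)
    return ax


def plot_weight_map(weight_map, class_idx=0, ax=None):
    """Heatmap of per-fold normalized channel weights for one classifier."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(weight_map.norm_weight[:, class_idx, :], aspect="auto",
                   cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("channel")
    ax.set_ylabel("CV fold")
    ax.set_title(str(weight_map.classes[class_idx]))
    plt.colorbar(im, ax=ax, label="normalized |weight|")
    return ax


def plot_connectivity(conn, ax=None):
    """Correlation matrix with seed rows marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(conn.cc, cmap="RdBu_r", vmin=-1, vmax=1)
    for s in conn.seeds:
        ax.axhline(s, color="k", lw=0.4)
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    plt.colorbar(im, ax=ax, label="CC")
    return ax
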