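"""Minimal disk scatter plot."""

from __future__ import annotations

import numpy as np


def plot_disk(Y, labels=None, ax=None, title: str | None = None):
    """Scatter an embedding inside the unit-circle boundary.

    ``Y`` is a PoincareEmbedding or an (n, 2) array; ``labels`` colors the
    points.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    pts = Y.Y if hasattr(Y, "Y") else np.asarray(Y, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="black", linewidth=0.8)
    if labels is None:
        ax.scatter(pts[:, 0], pts[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(pts[m, 0], pts[m, 1], s=12, label=str(lab))
        ax.legend(loc="upper right", fontsize=7)
    ax.set_aspect("equal")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axis("off")
    if title:
        ax.set_title(title)
    return ax
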