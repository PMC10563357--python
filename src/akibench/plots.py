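"""Reliability-curve and metric-comparison plots."""

from __future__ import annotations

from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def reliability_curve(probs, labels, n_bins: int = 10, path: Optional[str] = None):
    """Binned observed event rate vs mean predicted probability."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    bins = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            xs.append(probs[mask].mean())
            ys.append(labels[mask].mean())
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect")
    ax.plot(xs, ys, "o-", label="model")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed AKI rate")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def f1_comparison(groups: Dict[str, np.ndarray], path: Optional[str] = None):
    """Box plot of bootstrap f1 distributions per baseline method."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
    ax.set_ylabel("bootstrap f1")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
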