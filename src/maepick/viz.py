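"""Minimal plotting helpers for inspecting picks and score maps."""

from __future__ import annotations

import numpy as np


def plot_picks(micrograph, pick_set=None, ground_truth=None, ax=None,
               diameter: float | None = None):
    """Show a micrograph with picked (and optionally true) centers.

    Picks are drawn as circles colored by score; ground truth as squares.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    img = micrograph.image
    lo, hi = np.percentile(img, [1, 99])
    ax.imshow(img, cmap="gray", vmin=lo, vmax=hi)
    if ground_truth is not None and len(ground_truth.centers):
        d = diameter or ground_truth.diameter
        for cx, cy in ground_truth.centers:
            ax.add_patch(plt.Rectangle((cx - d / 2, cy - d / 2), d, d,
                                       fill=False, color="tab:green", lw=1.0))
    if pick_set is not None and len(pick_set.picked_centers):
        sc = ax.scatter(pick_set.picked_centers[:, 0], pick_set.picked_centers[:, 1],
                        c=pick_set.picked_scores, cmap="autumn", s=30, marker="o",
                        edgecolors="tab:blue")
        plt.colorbar(sc, ax=ax, fraction=0.046, label="cosine score")
    ax.set_title(getattr(micrograph, "micrograph_id", ""))
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    return ax


def plot_score_histogram(scores, threshold: float | None = None, ax=None):
    """Histogram of window scores with the chosen cutoff marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(scores), bins=60, color="tab:gray")
    if threshold is not None:
        ax.axvline(threshold, color="tab:red", label=f"threshold {threshold:.3f}")
        ax.legend()
    ax.set_xlabel("max cosine similarity")
    ax.set_ylabel("windows")
    return ax
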