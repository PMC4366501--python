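"""Figures for the pipeline's main outputs.

All functions draw onto a provided axes or create one, and return the
axes so callers can compose panels; nothing here touches the screen
(Agg-safe).
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .coactivity import CdfEnvelope, CoactivityNull
from .core import PointPattern

__all__ = [
    "plot_activity_map",
    "plot_coactive_count_histogram",
    "plot_distance_cdf",
]


def plot_activity_map(
    pattern: PointPattern, ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Scatter a fibre map in molecular-layer coordinates; points labelled
    ``responding`` are filled, others open."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    r = pattern.region
    ax.add_patch(
        plt.Rectangle(
            (r.x0, r.y0), r.width, r.height, fill=False, ec="0.6", lw=0.8
        )
    )
    if pattern.labels is not None:
        responding = pattern.labels == "responding"
    else:
        responding = np.zeros(pattern.n_points, dtype=bool)
    ax.scatter(
        pattern.points[~responding, 0],
        pattern.points[~responding, 1],
        facecolors="none",
        edgecolors="k",
        s=25,
        label="labelled",
    )
    if responding.any():
        ax.scatter(
            pattern.points[responding, 0],
            pattern.points[responding, 1],
            c="crimson",
            s=30,
            label="responding",
        )
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("sagittal x (μm)")
    ax.set_ylabel("molecular-layer depth y (μm)")
    ax.set_aspect("equal")
    return ax


def plot_coactive_count_histogram(
    null: CoactivityNull,
    observed_counts: np.ndarray,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Observed number of co-active fibres per FOV against the pooled
    binomial expectation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    kmax = len(null.expected_histogram) - 1
    ks = np.arange(kmax + 1)
    obs = np.bincount(np.asarray(observed_counts, dtype=int), minlength=kmax + 1)
    ax.bar(ks - 0.2, obs, width=0.4, label="observed", color="crimson")
    ax.bar(
        ks + 0.2,
        null.expected_histogram,
        width=0.4,
        label=f"binomial (p={null.p_response:.3g})",
        color="0.6",
    )
    ax.set_xlabel("co-active fibres per FOV")
    ax.set_ylabel("fields of view")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_distance_cdf(
    envelope: CdfEnvelope,
    active_distances: Optional[np.ndarray] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """All-pair distance CDF with its confidence envelope and, optionally,
    the active-pair CDF on top."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(
        envelope.grid_um,
        envelope.lower,
        envelope.upper,
        alpha=0.3,
        color="0.5",
        label=f"{100 * envelope.coverage:.1f}% envelope",
    )
    ax.plot(envelope.grid_um, envelope.expected_cdf, "k-", lw=1, label="all pairs")
    if active_distances is not None and len(active_distances):
        d = np.sort(np.asarray(active_distances))
        cdf = np.searchsorted(d, envelope.grid_um, side="right") / d.size
        ax.plot(envelope.grid_um, cdf, "-", c="crimson", lw=1.5, label="active pairs")
    ax.set_xlabel("pair distance (μm)")
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False, fontsize=8)
    return ax
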