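"""Minimal plots: Mantel correlogram and elimination trajectory."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .mantel import CorrelogramResult
from .selection import EliminationTrace


def plot_correlogram(result: CorrelogramResult, alpha: float = 0.05, ax=None):
    """Mantel r per distance class; filled markers are significant after
    multiple-test correction."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mids = [(lo + hi) / 2 for lo, hi, _ in result.classes]
    sig = result.significant(alpha)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(mids, result.r_per_class, "-", color="C0", zorder=1)
    ax.scatter(
        [m for m, s in zip(mids, sig) if s],
        [r for r, s in zip(result.r_per_class, sig) if s],
        marker="s", color="C0", zorder=2, label=f"corrected p <= {alpha}",
    )
    ax.scatter(
        [m for m, s in zip(mids, sig) if not s],
        [r for r, s in zip(result.r_per_class, sig) if not s],
        marker="s", facecolors="none", edgecolors="C0", zorder=2,
    )
    ax.set_xlabel("distance class midpoint")
    ax.set_ylabel("Mantel r")
    ax.legend(loc="best", frameon=False)
    return ax


def plot_trajectory(trace: EliminationTrace, ax=None):
    """Mantel r across elimination iterations, peak marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(trace.r_trajectory.size), trace.r_trajectory, color="C1")
    ax.axvline(trace.peak_index, color="grey", ls="--", lw=0.8)
    ax.annotate(
        f"peak r={trace.peak_r:.3f}\n{len(trace.peak_set)} series",
        (trace.peak_index, trace.peak_r),
        textcoords="offset points", xytext=(6, -12), fontsize=8,
    )
    ax.set_xlabel("series removed")
    ax.set_ylabel("Mantel r")
    return ax
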