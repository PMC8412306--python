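"""Matplotlib helpers: significance heatmap, curve panels, spatial maps.

The spatial map places each subgroup's metric at the midpoint of its two
stimulated electrodes (subgroup labels of the form ``E01-E02`` are resolved
against a BIDS-style electrode table), colored by assigned curve with marker
size and intensity proportional to the metric; excluded subgroups are gray.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .basis import BPCSet  # noqa: E402
from .factorization import ClusterAssignment  # noqa: E402
from .significance import SignificanceMatrix  # noqa: E402

__all__ = ["plot_significance_matrix", "plot_bpcs", "plot_spatial_map"]

_CLUSTER_COLORS = plt.get_cmap("tab10").colors


def plot_significance_matrix(xi: SignificanceMatrix, ax=None):
    """Heatmap of the N x N significance matrix with subgroup tick labels."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(xi.values, cmap="hot", vmin=0, vmax=1)
    ticks = np.arange(xi.labels.size)
    ax.set_xticks(ticks, [str(x) for x in xi.labels], rotation=90, fontsize=6)
    ax.set_yticks(ticks, [str(x) for x in xi.labels], fontsize=6)
    ax.set_xlabel("raw-trial subgroup m")
    ax.set_ylabel("normalized-trial subgroup n")
    plt.colorbar(im, ax=ax, label="scaled t-value")
    return ax


def plot_bpcs(bpcs: BPCSet, axes=None):
    """One panel per basis profile curve."""
    n = bpcs.n_curves
    if axes is None:
        _, axes = plt.subplots(n, 1, figsize=(6, 2 * n), sharex=True, squeeze=False)
        axes = axes[:, 0]
    for q, ax in enumerate(axes):
        ax.plot(bpcs.time, bpcs.curves[:, q],
                color=_CLUSTER_COLORS[q % len(_CLUSTER_COLORS)])
        ax.axhline(0, color="0.7", lw=0.5)
        ax.set_ylabel(f"B{q + 1}")
    axes[-1].set_xlabel("time after pulse (s)")
    return axes


def _pair_midpoint(label: str, electrodes: pd.DataFrame) -> np.ndarray | None:
    names = list(electrodes["name"].astype(str))
    parts = str(label).split("-")
    if len(parts) != 2 or not all(p in names for p in parts):
        return None
    xyz = electrodes.set_index("name").loc[parts, ["x", "y", "z"]].to_numpy(float)
    return xyz.mean(axis=0)


def plot_spatial_map(
    summary: pd.DataFrame,
    electrodes: pd.DataFrame,
    assignment: ClusterAssignment,
    metric: str = "snr_mean",
    ax=None,
):
    """2-D scatter of a per-subgroup metric at stimulation-pair midpoints.

    Each cluster's metric is scaled to its own maximum; excluded subgroups
    are drawn as small gray dots, electrodes as open circles.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(electrodes["x"], electrodes["y"], facecolors="none",
               edgecolors="0.6", s=30, zorder=1)
    per_cluster_max = summary[summary["bpc"] >= 0].groupby("bpc")[metric].max()
    for _, row in summary.iterrows():
        mid = _pair_midpoint(row["subgroup"], electrodes)
        if mid is None:
            continue
        q = int(row["bpc"])
        if q < 0:
            ax.scatter(*mid[:2], color="0.5", s=15, zorder=2)
            continue
        peak = per_cluster_max.get(q, np.nan)
        rel = row[metric] / peak if peak and np.isfinite(peak) and peak > 0 else 0.0
        rel = float(np.clip(rel, 0.05, 1.0))
        color = _CLUSTER_COLORS[q % len(_CLUSTER_COLORS)]
        ax.scatter(*mid[:2], color=color, alpha=0.3 + 0.7 * rel,
                   s=40 + 260 * rel, zorder=3)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax
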