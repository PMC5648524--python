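"""Figure-style outputs: ΔF/F₀ traces with detected peaks, network plots
in slice coordinates, and condition boxplots."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .network import FunctionalNetwork, edge_type
from .traces import process_trace
from .types import SliceRecording


def plot_traces(recording: SliceRecording, cells: Sequence[int],
                mark_peaks: bool = True, ax: Optional[plt.Axes] = None):
    """Stacked filtered ΔF/F₀ traces with arrowhead peak markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.2 * len(cells) + 1))
    offset = 0.0
    for i in cells:
        stats = process_trace(recording.traces[i])
        from .traces import bandpass, compute_dff

        filt = bandpass(compute_dff(recording.traces[i]))
        t = filt.times_s
        ax.plot(t, filt.values + offset, lw=0.8,
                color="tab:green" if recording.gfap_positive[i] else "tab:blue")
        if mark_peaks and stats.n_peaks:
            idx = np.searchsorted(t, stats.peak_times_s)
            ax.plot(stats.peak_times_s, filt.values[np.clip(idx, 0, t.size - 1)]
                    + offset + 0.05, marker=7, ls="none", ms=5, color="k")
        offset += max(0.6, 1.2 * np.ptp(filt.values))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ΔF/F₀ (offset per cell)")
    return ax


def plot_network(network: FunctionalNetwork, ax: Optional[plt.Axes] = None):
    """Nodes at their slice positions (µm); warmer edges = higher r."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = network.graph
    cmap = plt.get_cmap("YlOrRd")
    for u, v, d in g.edges(data=True):
        x = [g.nodes[u]["pos"][0], g.nodes[v]["pos"][0]]
        y = [g.nodes[u]["pos"][1], g.nodes[v]["pos"][1]]
        style = "-" if edge_type(g, u, v) != "mixed" else "--"
        ax.plot(x, y, style, color=cmap(d["r"]), lw=0.8, alpha=0.8)
    for n, d in g.nodes(data=True):
        ax.plot(*d["pos"], "o", ms=5,
                color="tab:green" if d["gfap_positive"] else "tab:blue")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.set_title(f"cutoff r ≥ {network.cutoff:.2f} ({network.cutoff_method})")
    return ax


def plot_condition_box(summary_table: pd.DataFrame, value: str,
                       by: str, ax: Optional[plt.Axes] = None):
    """Boxplot of per-slice values grouped by a condition column."""
    if ax is None:
        _, ax = plt.subplots()
    groups = [g[value].dropna().to_numpy()
              for _, g in summary_table.groupby(by)]
    labels = [str(k) for k, _ in summary_table.groupby(by)]
    ax.boxplot(groups, tick_labels=labels, showmeans=True)
    ax.set_ylabel(value)
    return ax
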