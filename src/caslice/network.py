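"""Correlation-thresholded functional networks and their metrics.

Edges connect active-cell pairs whose band-passed ΔF/F₀ traces correlate
above a cut-off; the cut-off is either fixed or derived from a circular-shift
surrogate distribution.  Networks partition into an astrocytic (GFAP+)
subgraph, a neuronal (GFAP−) subgraph, and the mixed edges joining them;
cluster metrics follow the functional analogue of Hartelt's definition — a
connected component of at least two cells within a label-restricted
subgraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .traces import DEFAULT_BAND_HZ, filtered_dff_matrix
from .types import SliceRecording

METHOD_ZERO_LAG = "zero-lag"
METHOD_MAX_LAG = "max-lag"

EDGE_ASTRO = "astro_astro"
EDGE_NEURON = "neuron_neuron"
EDGE_MIXED = "mixed"


@dataclass
class CorrelationMatrix:
    """Pairwise correlations over active cells."""

    r: np.ndarray
    cell_indices: list[int]  # indices into the recording's cell list
    cell_ids: list[str]
    method: str = METHOD_ZERO_LAG
    lag_window_s: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.cell_indices)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")


@dataclass
class FunctionalNetwork:
    """Thresholded correlation graph with typed, positioned nodes."""

    graph: nx.Graph
    cutoff: float
    cutoff_method: str = "fixed"
    corr_method: str = METHOD_ZERO_LAG

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class SubnetworkMetrics:
    """Cluster statistics of one label-restricted subgraph."""

    n_clusters: int
    cells_per_cluster: float  # NaN when no clusters
    connections_per_cell: float  # NaN when no clusters
    cluster_sizes: list[int] = field(default_factory=list)


def _epoch_slice(n_samples: int, sampling_interval_s: float,
                 epoch: Optional[tuple[float, float]]) -> slice:
    if epoch is None:
        return slice(0, n_samples)
    i0 = int(np.floor(epoch[0] / sampling_interval_s))
    i1 = int(np.ceil(epoch[1] / sampling_interval_s))
    if i1 <= i0:
        raise ValueError("zero-length epoch")
    return slice(max(i0, 0), min(i1, n_samples))


def _max_lag_corr(mat: np.ndarray, max_shift: int) -> np.ndarray:
    """Max Pearson r over integer-sample shifts in [-max_shift, max_shift]."""
    n = mat.shape[0]
    best = np.full((n, n), -np.inf)
    for s in range(-max_shift, max_shift + 1):
        if s == 0:
            a, b = mat, mat
        elif s > 0:
            a, b = mat[:, :-s], mat[:, s:]
        else:
            a, b = mat[:, -s:], mat[:, :s]
        az = (a - a.mean(axis=1, keepdims=True))
        bz = (b - b.mean(axis=1, keepdims=True))
        denom = np.outer(np.linalg.norm(az, axis=1), np.linalg.norm(bz, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = az @ bz.T / denom
        best = np.maximum(best, r)
    best = np.maximum(best, best.T)
    np.fill_diagonal(best, 1.0)
    return best


def correlate(
    recording: SliceRecording,
    active_cells: Sequence[int],
    epoch: Optional[tuple[float, float]] = None,
    method: str = METHOD_ZERO_LAG,
    lag_window_s: float = 4.0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> CorrelationMatrix:
    """Pairwise correlation of band-passed ΔF/F₀ traces over an epoch.

    ``zero-lag`` computes plain Pearson r; ``max-lag`` the maximum Pearson r
    over integer-sample shifts within ±``lag_window_s``.  Constant traces
    (undefined r) are excluded with a warning.
    """
    active_cells = list(active_cells)
    if len(active_cells) < 2:
        raise ValueError("need at least two active cells")
    mat = filtered_dff_matrix(recording, active_cells, band_hz)
    sl = _epoch_slice(mat.shape[1], recording.sampling_interval_s, epoch)
    mat = mat[:, sl]

    sds = mat.std(axis=1)
    ok = sds > 0
    if not ok.all():
        dropped = [recording.cell_ids[active_cells[i]]
                   for i in np.flatnonzero(~ok)]
        warnings.warn(f"excluding constant traces from correlation: {dropped}")
        active_cells = [c for c, keep in zip(active_cells, ok) if keep]
        mat = mat[ok]

    if method == METHOD_ZERO_LAG:
        r = np.corrcoef(mat)
        lag_window_s = 0.0
    elif method == METHOD_MAX_LAG:
        max_shift = int(round(lag_window_s / recording.sampling_interval_s))
        r = _max_lag_corr(mat, max_shift)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        r=r, cell_indices=active_cells,
        cell_ids=[recording.cell_ids[i] for i in active_cells],
        method=method, lag_window_s=lag_window_s)


def surrogate_cutoff(
    recording: SliceRecording,
    active_cells: Sequence[int],
    n_shuffles: int = 200,
    percentile: float = 99.0,
    seed: int = 0,
    epoch: Optional[tuple[float, float]] = None,
    method: str = METHOD_ZERO_LAG,
    lag_window_s: float = 4.0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> float:
    """Correlation cut-off from circularly time-shifted surrogate pairs.

    Each surrogate draws a random active-cell pair, circularly shifts one
    trace by a random offset (destroying alignment, preserving
    autocorrelation), and computes the correlation with the same method as
    the real analysis; the cut-off is the requested percentile of the
    surrogate distribution.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable percentile")
    active_cells = list(active_cells)
    if len(active_cells) < 2:
        raise ValueError("need at least two active cells")
    mat = filtered_dff_matrix(recording, active_cells, band_hz)
    sl = _epoch_slice(mat.shape[1], recording.sampling_interval_s, epoch)
    mat = mat[:, sl]
    n_samples = mat.shape[1]
    min_shift = max(1, int(round(10.0 / recording.sampling_interval_s)))
    if n_samples <= 2 * min_shift:
        raise ValueError("too few samples for circular shifts")
    rng = np.random.default_rng(seed)
    max_shift = int(round(lag_window_s / recording.sampling_interval_s))

    rs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        i, j = rng.choice(len(active_cells), size=2, replace=False)
        shift = int(rng.integers(min_shift, n_samples - min_shift))
        y = np.roll(mat[j], shift)
        if method == METHOD_ZERO_LAG:
            rs[k] = np.corrcoef(mat[i], y)[0, 1]
        else:
            pair = np.vstack([mat[i], y])
            rs[k] = _max_lag_corr(pair, max_shift)[0, 1]
    return float(np.percentile(rs, percentile))


def build_network(
    corr: CorrelationMatrix,
    cutoff: float,
    positions: np.ndarray,
    gfap_positive: np.ndarray,
    cutoff_method: str = "fixed",
) -> FunctionalNetwork:
    """Graph with edges exactly {(i, j): r_ij ≥ cutoff, i < j}.

    ``positions`` and ``gfap_positive`` are indexed by the recording's cell
    indices; node attributes carry position (µm) and cell type for plotting
    and partitioning.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    g = nx.Graph()
    for k, idx in enumerate(corr.cell_indices):
        g.add_node(idx, cell_id=corr.cell_ids[k],
                   pos=tuple(np.asarray(positions)[idx]),
                   gfap_positive=bool(np.asarray(gfap_positive)[idx]))
    n = len(corr.cell_indices)
    for a in range(n):
        for b in range(a + 1, n):
            if corr.r[a, b] >= cutoff:
                g.add_edge(corr.cell_indices[a], corr.cell_indices[b],
                           r=float(corr.r[a, b]))
    return FunctionalNetwork(graph=g, cutoff=cutoff,
                             cutoff_method=cutoff_method,
                             corr_method=corr.method)


def edge_type(graph: nx.Graph, u, v) -> str:
    a = graph.nodes[u]["gfap_positive"]
    b = graph.nodes[v]["gfap_positive"]
    if a and b:
        return EDGE_ASTRO
    if not a and not b:
        return EDGE_NEURON
    return EDGE_MIXED


def partition(network: FunctionalNetwork) -> tuple[nx.Graph, nx.Graph, list]:
    """(astro subgraph, neuron subgraph, mixed edge list).

    The astro subgraph is induced on GFAP+ nodes, the neuron subgraph on
    GFAP− nodes; mixed edges have one endpoint of each type.  The three edge
    sets partition the network's edges.
    """
    g = network.graph
    astro_nodes = [n for n, d in g.nodes(data=True) if d["gfap_positive"]]
    neuron_nodes = [n for n, d in g.nodes(data=True) if not d["gfap_positive"]]
    astro = g.subgraph(astro_nodes).copy()
    neuron = g.subgraph(neuron_nodes).copy()
    mixed = [(u, v) for u, v in g.edges if edge_type(g, u, v) == EDGE_MIXED]
    return astro, neuron, mixed


def cluster_metrics(subgraph: nx.Graph) -> SubnetworkMetrics:
    """Cluster statistics: components of size ≥ 2 within a subgraph.

    ``cells_per_cluster`` is the mean component size, ``connections_per_cell``
    the mean subgraph degree over nodes belonging to clusters.  With no
    clusters both are NaN.
    """
    sizes = [len(c) for c in nx.connected_components(subgraph) if len(c) >= 2]
    if not sizes:
        return SubnetworkMetrics(n_clusters=0, cells_per_cluster=float("nan"),
                                 connections_per_cell=float("nan"))
    clustered = [n for c in nx.connected_components(subgraph) if len(c) >= 2
                 for n in c]
    degrees = [subgraph.degree(n) for n in clustered]
    return SubnetworkMetrics(
        n_clusters=len(sizes),
        cells_per_cluster=float(np.mean(sizes)),
        connections_per_cell=float(np.mean(degrees)),
        cluster_sizes=sorted(sizes, reverse=True),
    )


def edge_fractions(network: FunctionalNetwork) -> dict[str, float]:
    """Fractions of astro-astro, neuron-neuron and mixed correlating pairs."""
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    counts = {EDGE_ASTRO: 0, EDGE_NEURON: 0, EDGE_MIXED: 0}
    for u, v in g.edges:
        counts[edge_type(g, u, v)] += 1
    total = g.number_of_edges()
    return {k: c / total for k, c in counts.items()}


def infer_network(
    recording: SliceRecording,
    active_cells: Sequence[int],
    epoch: Optional[tuple[float, float]] = None,
    method: str = METHOD_ZERO_LAG,
    cutoff: Optional[float] = None,
    surrogate_percentile: float = 99.0,
    n_shuffles: int = 200,
    seed: int = 0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> FunctionalNetwork:
    """Convenience chain: correlate → cut-off → build_network.

    With ``cutoff=None`` the surrogate cut-off is used (circular shift,
    given percentile); otherwise the fixed value.
    """
    corr = correlate(recording, active_cells, epoch, method, band_hz=band_hz)
    if cutoff is None:
        cut = surrogate_cutoff(recording, active_cells, n_shuffles,
                               surrogate_percentile, seed, epoch, method,
                               band_hz=band_hz)
        cutoff_method = f"surrogate:{surrogate_percentile:g}"
    else:
        cut, cutoff_method = cutoff, "fixed"
    return build_network(corr, cut, recording.positions,
                         recording.gfap_positive, cutoff_method)
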