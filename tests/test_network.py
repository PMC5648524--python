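"""Network inference: correlations, surrogate cut-off, thresholding,
partition and cluster metrics against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caslice.network import (
    CorrelationMatrix,
    build_network,
    cluster_metrics,
    correlate,
    edge_fractions,
    infer_network,
    partition,
    surrogate_cutoff,
)
from caslice.synthetic import generate_slice
from caslice.types import NEURON, PopulationSpec


def noise_recording(n_cells=12, seed=0, duration_s=300.0):
    """Active-labelled cells carrying pure white-noise traces."""
    pops = [PopulationSpec(NEURON, n_cells, 0.0, 5.0, 1.0, noise_sd=0.03)]
    return generate_slice(pops, duration_s=duration_s, seed=seed)


def random_corr_matrix(rng, n):
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, cell_indices=list(range(n)),
                             cell_ids=[f"c{i}" for i in range(n)])


# --- correlation ----------------------------------------------------------

def test_correlation_matrix_symmetry_and_unit_diagonal(prebotc_control):
    rec = prebotc_control
    act = list(np.flatnonzero(rec.ground_truth.active))[:40]
    corr = correlate(rec, act)
    assert np.allclose(corr.r, corr.r.T)
    assert np.allclose(np.diag(corr.r), 1.0)
    assert np.all(np.abs(corr.r) <= 1.0 + 1e-12)


def test_trace_against_itself_has_unit_correlation(prebotc_control):
    rec = prebotc_control
    i = int(np.flatnonzero(rec.ground_truth.active)[0])
    corr = correlate(rec, [i, i])
    assert corr.r[0, 1] == pytest.approx(1.0)


def test_independent_noise_traces_match_analytic_null():
    """|r| of independent filtered noise stays within a few analytic null
    SDs (~1/√n_eff); far below any meaningful cut-off."""
    rec = noise_recording(n_cells=14, seed=2)
    corr = correlate(rec, list(range(14)))
    off = corr.r[np.triu_indices(14, 1)]
    # band-passing leaves ~0.14 of the bandwidth -> n_eff ~ 600 * 0.14
    null_sd = 1.0 / np.sqrt(600 * 0.14)
    assert np.percentile(np.abs(off), 99) < 5 * null_sd


def test_assembly_members_correlate_near_target(prebotc_control):
    rec = prebotc_control
    gt = rec.ground_truth
    # assembly 4 is a pure neuron assembly in the preBötC plan
    members = np.flatnonzero((gt.assembly_id == 4) & ~rec.gfap_positive)
    corr = correlate(rec, list(members))
    off = corr.r[np.triu_indices(len(members), 1)]
    assert 0.6 <= off.mean() <= 0.95


def test_constant_trace_excluded_with_warning():
    rec = noise_recording(n_cells=4, seed=3)
    rec.traces[2].values[:] = 100.0  # constant cell
    with pytest.warns(UserWarning, match="constant"):
        corr = correlate(rec, [0, 1, 2, 3])
    assert len(corr.cell_indices) == 3
    assert 2 not in corr.cell_indices


def test_max_lag_correlation_bounds_zero_lag(prebotc_control):
    rec = prebotc_control
    act = list(np.flatnonzero(rec.ground_truth.active))[:20]
    r0 = correlate(rec, act, method="zero-lag")
    rl = correlate(rec, act, method="max-lag", lag_window_s=4.0)
    off = np.triu_indices(len(act), 1)
    assert np.all(rl.r[off] >= r0.r[off] - 1e-9)


# --- surrogate cut-off ----------------------------------------------------

def test_surrogate_cutoff_reproducible_and_below_one(prebotc_control):
    rec = prebotc_control
    act = list(np.flatnonzero(rec.ground_truth.active))[:30]
    c1 = surrogate_cutoff(rec, act, n_shuffles=200, seed=5)
    c2 = surrogate_cutoff(rec, act, n_shuffles=200, seed=5)
    assert c1 == c2
    assert 0.0 < c1 < 1.0
    with pytest.raises(ValueError):
        surrogate_cutoff(rec, act, n_shuffles=50, seed=5)


def test_surrogate_cutoff_on_identical_traces_below_one():
    """Circular shifting breaks alignment even for identical cells."""
    rec = noise_recording(n_cells=2, seed=7)
    rec.traces[1].values[:] = rec.traces[0].values
    cut = surrogate_cutoff(rec, [0, 1], n_shuffles=200, seed=1)
    assert cut < 1.0


def test_pure_noise_yields_about_one_percent_edges_at_99th_percentile():
    """By construction of the percentile, ~1% of independent pairs exceed
    the 99th-percentile surrogate cut-off."""
    rates = []
    for seed in range(5):
        rec = noise_recording(n_cells=16, seed=20 + seed)
        cells = list(range(16))
        cut = surrogate_cutoff(rec, cells, n_shuffles=400, percentile=99.0,
                               seed=seed)
        corr = correlate(rec, cells)
        off = corr.r[np.triu_indices(16, 1)]
        rates.append(np.mean(off >= cut))
    assert np.mean(rates) == pytest.approx(0.01, abs=0.02)


# --- thresholding ---------------------------------------------------------

def test_build_network_edge_set_extremes(rng):
    corr = random_corr_matrix(rng, 10)
    positions = rng.uniform(0, 1000, (10, 2))
    labels = rng.uniform(size=10) < 0.5
    none = build_network(corr, 1.0, positions, labels)
    assert none.n_edges <= np.sum(corr.r[np.triu_indices(10, 1)] >= 1.0)
    full = build_network(corr, 1e-9, positions, labels)
    # every pair with r >= ~0 qualifies; with r>=cutoff→0+ all positive pairs
    expected = np.sum(corr.r[np.triu_indices(10, 1)] >= 1e-9)
    assert full.n_edges == expected
    with pytest.raises(ValueError):
        build_network(corr, 0.0, positions, labels)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000),
       c1=st.floats(0.05, 0.95), c2=st.floats(0.05, 0.95))
def test_threshold_monotonicity(seed, c1, c2):
    """Raising the cut-off never adds edges (checked by brute force)."""
    rng = np.random.default_rng(seed)
    corr = random_corr_matrix(rng, 12)
    positions = rng.uniform(0, 1000, (12, 2))
    labels = rng.uniform(size=12) < 0.5
    lo, hi = sorted((c1, c2))
    e_lo = set(build_network(corr, lo, positions, labels).graph.edges)
    e_hi = set(build_network(corr, hi, positions, labels).graph.edges)
    assert e_hi <= e_lo
    # brute-force double loop oracle for the low cut-off
    brute = {(i, j) for i in range(12) for j in range(i + 1, 12)
             if corr.r[i, j] >= lo}
    assert {tuple(sorted(e)) for e in e_lo} == brute


# --- partition and metrics ------------------------------------------------

def graph_from_edges(n, edges, astro_flags):
    corr = CorrelationMatrix(r=np.eye(n), cell_indices=list(range(n)),
                             cell_ids=[f"c{i}" for i in range(n)])
    for i, j in edges:
        corr.r[i, j] = corr.r[j, i] = 0.9
    return build_network(corr, 0.5, np.zeros((n, 2)),
                         np.asarray(astro_flags, bool))


def test_partition_all_neuron_network_has_no_astro_or_mixed():
    net = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)], [False] * 4)
    astro, neuron, mixed = partition(net)
    assert astro.number_of_edges() == 0 and not mixed
    assert neuron.number_of_edges() == 3
    fr = edge_fractions(net)
    assert fr["neuron_neuron"] == pytest.approx(1.0)


def test_partition_completeness_on_preset_network(prebotc_control):
    rec = prebotc_control
    act = list(np.flatnonzero(rec.ground_truth.active))
    net = infer_network(rec, act, seed=0, n_shuffles=400,
                        surrogate_percentile=99.5)
    astro, neuron, mixed = partition(net)
    assert (astro.number_of_edges() + neuron.number_of_edges()
            + len(mixed)) == net.n_edges


def test_edge_fractions_hand_built_graph():
    """2 astro-astro, 5 neuron-neuron, 3 mixed edges → (0.2, 0.5, 0.3)."""
    astro = [True, True, True, False, False, False, False, False]
    edges = [(0, 1), (1, 2),  # astro-astro
             (3, 4), (4, 5), (5, 6), (6, 7), (3, 7),  # neuron-neuron
             (0, 3), (1, 4), (2, 5)]  # mixed
    net = graph_from_edges(8, edges, astro)
    fr = edge_fractions(net)
    assert fr["astro_astro"] == pytest.approx(0.2)
    assert fr["neuron_neuron"] == pytest.approx(0.5)
    assert fr["mixed"] == pytest.approx(0.3)
    with pytest.raises(ValueError):
        edge_fractions(graph_from_edges(3, [], [True, False, False]))


def test_cluster_metrics_isolated_node_and_cycle():
    g = nx.Graph()
    g.add_node(0)
    m = cluster_metrics(g)
    assert m.n_clusters == 0 and np.isnan(m.cells_per_cluster)
    cycle = nx.cycle_graph(5)
    m = cluster_metrics(cycle)
    assert m.n_clusters == 1
    assert m.cells_per_cluster == pytest.approx(5.0)
    assert m.connections_per_cell == pytest.approx(2.0)


def dfs_components(nodes, edges):
    """Independent depth-first-search component oracle."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return sorted(len(c) for c in comps if len(c) >= 2)


@pytest.mark.parametrize("seed", range(8))
def test_cluster_metrics_match_dfs_oracle_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 51))
    p = rng.uniform(0.02, 0.15)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
    m = cluster_metrics(g)
    oracle = dfs_components(list(g.nodes), list(g.edges))
    assert sorted(m.cluster_sizes) == oracle
    if oracle:
        assert m.cells_per_cluster == pytest.approx(np.mean(oracle))
        clustered = [v for comp_size, comp in
                     [(len(c), c) for c in nx.connected_components(g)]
                     if comp_size >= 2 for v in comp]
        assert m.connections_per_cell == pytest.approx(
            np.mean([g.degree(v) for v in clustered]))


def test_planted_two_assembly_network_partitions_cleanly():
    """One pure-astro and one pure-neuron assembly, no cross edges."""
    from caslice.types import ASTROCYTE, AssemblyPlan, CouplingSpec

    pops = [
        PopulationSpec(ASTROCYTE, 5, 1.0, 1.1, 0.2, ipi_cv=25.0),
        PopulationSpec(NEURON, 5, 1.0, 5.4, 0.5, ipi_cv=25.0),
    ]
    coupling = CouplingSpec(assembly_plan=[AssemblyPlan(5, 0),
                                           AssemblyPlan(0, 5)],
                            within_assembly_corr=0.9)
    rec = generate_slice(pops, coupling, duration_s=900.0, seed=21)
    net = infer_network(rec, list(range(10)), seed=3, n_shuffles=2000,
                        surrogate_percentile=100.0)
    astro, neuron, mixed = partition(net)
    assert not mixed
    assert astro.number_of_edges() == 10  # complete K5
    assert neuron.number_of_edges() == 10
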