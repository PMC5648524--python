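"""Generator contracts: determinism, planted rates, locking, IHC planting."""

import numpy as np
import pytest

from caslice.synthetic import (
    IHC_CHANNEL_A,
    IHC_CHANNEL_B,
    gamma_train,
    generate_ihc_stack,
    generate_pge2,
    generate_preset_slice,
    generate_slice,
    paper_preset,
    planted_mask,
)
from caslice.types import (
    ASTROCYTE,
    NEURON,
    AssemblyPlan,
    CouplingSpec,
    PopulationSpec,
    StimulusProtocol,
)


def test_identical_seed_gives_bitwise_identical_recordings():
    pops, coupling, protocol = paper_preset("pFRG/RTN", "control")
    a = generate_slice(pops, coupling, protocol, duration_s=120.0, seed=7)
    b = generate_slice(pops, coupling, protocol, duration_s=120.0, seed=7)
    assert np.array_equal(a.values_matrix(), b.values_matrix())
    assert np.array_equal(a.positions, b.positions)
    assert all(np.array_equal(x, y) for x, y in
               zip(a.ground_truth.peak_times_s, b.ground_truth.peak_times_s))


def test_pfrg_preset_astrocyte_proportion():
    """The pFRG/RTN network is ~70% astrocytes; the preBötC ~61%."""
    rec = generate_preset_slice("pFRG/RTN", "control", seed=1)
    assert rec.gfap_positive.mean() == pytest.approx(0.70, abs=0.02)
    rec = generate_preset_slice("preBotC", "control", seed=1)
    assert rec.gfap_positive.mean() == pytest.approx(0.61, abs=0.02)


def test_single_neuron_spectral_peak_matches_planted_rate():
    """FFT oracle: a noise-free 5 cycles/min cell has its dominant spectral
    component at 5/60 Hz."""
    pops = [PopulationSpec(NEURON, n_cells=1, frac_active=1.0,
                           freq_mean=5.0, freq_sd=1e-6, ipi_cv=1.0,
                           noise_sd=0.0)]
    rec = generate_slice(pops, duration_s=600.0, seed=3)
    x = rec.traces[0].values - rec.traces[0].values.mean()
    freqs = np.fft.rfftfreq(x.size, d=0.5)
    power = np.abs(np.fft.rfft(x)) ** 2
    band = (freqs > 0.01) & (freqs < 0.3)
    dominant = freqs[band][np.argmax(power[band])]
    assert dominant == pytest.approx(5.0 / 60.0, rel=0.15)


def test_rate_fidelity_of_planted_peak_trains():
    """Noise-free single-cell peak count per minute equals the planted
    frequency within one peak over the recording."""
    for rate in (1.1, 5.4):
        pops = [PopulationSpec(NEURON, 1, 1.0, freq_mean=rate, freq_sd=1e-6,
                               ipi_cv=20.0, noise_sd=0.0)]
        counts = []
        for seed in range(10):
            rec = generate_slice(pops, duration_s=300.0, seed=seed)
            counts.append(len(rec.ground_truth.peak_times_s[0]))
        assert np.mean(counts) == pytest.approx(rate * 5.0, abs=1.0)


def test_lock_structure_astro_peaks_subset_of_neuron_master():
    """With lock ratio 2 and zero jitter, every astrocytic peak coincides
    with a neuronal peak and counts are in a 1:2 ratio (±1)."""
    pops = [
        PopulationSpec(ASTROCYTE, 2, 1.0, freq_mean=2.0, freq_sd=1e-6,
                       ipi_cv=20.0, noise_sd=0.0),
        PopulationSpec(NEURON, 3, 1.0, freq_mean=4.0, freq_sd=1e-6,
                       ipi_cv=20.0, noise_sd=0.0),
    ]
    coupling = CouplingSpec(assembly_plan=[AssemblyPlan(2, 3, locked=True)],
                            within_assembly_corr=1.0,
                            astro_neuron_lock_ratio=2, lock_jitter=0.0)
    rec = generate_slice(pops, coupling, duration_s=600.0, seed=9)
    gt = rec.ground_truth
    astro = np.flatnonzero(rec.gfap_positive)
    neuron = np.flatnonzero(~rec.gfap_positive)
    neuron_set = {round(t, 6) for t in gt.peak_times_s[neuron[0]]}
    for i in astro:
        assert gt.locked[i]
        assert all(round(t, 6) in neuron_set for t in gt.peak_times_s[i])
        n_ratio = len(gt.peak_times_s[neuron[0]]) / len(gt.peak_times_s[i])
        assert abs(len(gt.peak_times_s[neuron[0]])
                   - 2 * len(gt.peak_times_s[i])) <= 1, n_ratio


def test_generate_slice_input_validation():
    pops = [PopulationSpec(NEURON, 2, 1.0, 5.0, 1.0)]
    with pytest.raises(ValueError):
        generate_slice(pops, duration_s=0.0, seed=1)
    late = StimulusProtocol(kind="flrf", onset_s=200.0, duration_s=300.0)
    with pytest.raises(ValueError):
        generate_slice(pops, protocol=late, duration_s=300.0, seed=1)


def test_wt_genotype_forces_unit_multipliers():
    p = StimulusProtocol(kind="flrf", onset_s=10, duration_s=10,
                         astro_freq_multiplier=3.0,
                         neuron_freq_multiplier=2.0,
                         inactive_transient=True, genotype="WT")
    assert p.astro_freq_multiplier == 1.0
    assert p.neuron_freq_multiplier == 1.0
    assert not p.inactive_transient


def test_preset_parameters_match_reported_values():
    pops, coupling, protocol = paper_preset("pFRG/RTN", "control")
    astro = next(p for p in pops if p.label == ASTROCYTE)
    assert astro.freq_mean == pytest.approx(1.1)
    assert astro.frac_active == pytest.approx(0.18)
    _, _, flrf = paper_preset("preBotC", "flrf")
    assert flrf.neuron_freq_multiplier == 1.0  # preBötC neurons unaffected
    assert flrf.astro_freq_multiplier == 3.0
    _, _, wt = paper_preset("pFRG/RTN", "wt_flrf")
    assert wt.astro_freq_multiplier == 1.0
    with pytest.raises(ValueError):
        paper_preset("pons", "control")
    with pytest.raises(ValueError):
        paper_preset("pFRG/RTN", "unknown")


def test_gamma_train_interval_cv_matches_target():
    rng = np.random.default_rng(0)
    t = gamma_train(rng, 30.0, 33.0, 0.0, 20000.0)
    iv = np.diff(t)
    assert 100.0 * iv.std() / iv.mean() == pytest.approx(33.0, abs=3.0)


# --- IHC stacks -----------------------------------------------------------

def brute_force_overlap_count(stack):
    """Oracle: count planted B ROIs whose voxel mask intersects any A mask."""
    shape = stack.shape
    a_union = np.zeros(shape, dtype=bool)
    for roi in stack.planted_rois[IHC_CHANNEL_A]:
        a_union |= planted_mask(roi, shape)
    hits = 0
    for roi in stack.planted_rois[IHC_CHANNEL_B]:
        if (planted_mask(roi, shape) & a_union).any():
            hits += 1
    return hits


@pytest.mark.parametrize("overlap,expect", [(0.0, "none"), (1.0, "all")])
def test_ihc_extreme_overlap_fractions(overlap, expect):
    stack = generate_ihc_stack((30, 12), overlap, 0.5, seed=2,
                               field_px=(128, 128))
    hits = brute_force_overlap_count(stack)
    planted = sum(r.overlaps_partner for r in stack.planted_rois[IHC_CHANNEL_B])
    assert hits == planted
    assert hits == (0 if expect == "none" else 12)


def test_ihc_planted_overlap_count_matches_mask_oracle():
    """Planted flags agree exactly with brute-force mask intersection, and
    the overlap count is binomial around overlap_fraction × n."""
    hits = []
    for seed in range(5):
        stack = generate_ihc_stack((60, 25), 0.92, 0.4, seed=seed,
                                   field_px=(160, 160))
        planted = sum(r.overlaps_partner
                      for r in stack.planted_rois[IHC_CHANNEL_B])
        assert brute_force_overlap_count(stack) == planted
        hits.append(planted)
    assert np.mean(hits) == pytest.approx(0.92 * 25, abs=2.0)


def test_ihc_determinism_and_validation():
    a = generate_ihc_stack((10, 5), 0.5, 0.5, seed=4, field_px=(96, 96))
    b = generate_ihc_stack((10, 5), 0.5, 0.5, seed=4, field_px=(96, 96))
    assert np.array_equal(a.channels[IHC_CHANNEL_A], b.channels[IHC_CHANNEL_A])
    with pytest.raises(ValueError):
        generate_ihc_stack((5, 5), 1.5, 0.5, seed=0)
    with pytest.raises(ValueError):
        generate_ihc_stack((5, 5), 0.5, 0.0, seed=0)
    with pytest.raises(ValueError):
        generate_ihc_stack((5, 5), 0.5, 0.5, seed=0, field_px=(8, 8),
                           cell_radius_um=10.0)


# --- PGE2 -----------------------------------------------------------------

def test_pge2_flat_when_fold_is_one():
    tc = generate_pge2(baseline_level=10.0, fold_change=1.0, onset_min=10,
                       transient_width_min=10, noise_sd=0.0, seed=0)
    assert np.allclose(tc.concentration, 10.0)


def test_pge2_noise_free_peak_is_exactly_fold_times_baseline():
    tc = generate_pge2(baseline_level=10.0, fold_change=2.0, onset_min=10,
                       transient_width_min=10, noise_sd=0.0, seed=0)
    assert tc.concentration.max() / 10.0 == pytest.approx(2.0, abs=1e-9)
    # returns to baseline by the end of the transient window
    assert tc.concentration[-1] == pytest.approx(10.0, abs=1e-9)
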