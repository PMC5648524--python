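"""Synthetic slice recordings, IHC stacks and PGE2 timecourses.

The generator emulates the statistical structure of two-population
(astrocyte/neuron) calcium recordings from organotypic brainstem slice
cultures: gamma-renewal calcium transient trains with population-specific
rates, a majority-inactive astrocyte pool, spatially embedded correlated
assemblies, partial astrocyte–neuron phase locking, and agonist (FLRF) /
hypercapnia stimulus responses.  Named presets reproduce the published
summary statistics of the pFRG/RTN and preBötC respiratory networks.

Calcium transients are fast-rise/exponential-decay kernels (rise 1 s,
decay 4 s) convolved with a jittered point process; inter-peak intervals
are gamma distributed with the shape set from the target CV, which gives
direct control of the interval-CV statistic the pipeline must recover.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .types import (
    ASTROCYTE,
    GENOTYPE_MRGA1,
    GENOTYPE_WT,
    NEURON,
    REGION_PFRG,
    REGION_PREBOTC,
    AssemblyPlan,
    CouplingSpec,
    FluorescenceTrace,
    GroundTruth,
    LabeledImageStack,
    Pge2Timecourse,
    PlantedRoi,
    PopulationSpec,
    SliceRecording,
    StimulusProtocol,
)

# Transient kernel defaults (s); fast rise / exponential decay, the shape of
# somatic dye transients, without claiming a biophysical model.  The decay is
# short enough that successive peaks at neuronal rates (5-8 cycles/min)
# remain resolvable after the 0.01-0.15 Hz analysis band-pass.
KERNEL_RISE_S = 1.0
KERNEL_DECAY_S = 1.5

# Spatial layout: cells in a 1000x1000 um field, assemblies within 150 um.
FIELD_UM = 1000.0
ASSEMBLY_RADIUS_UM = 150.0

BASELINE_OFFSET = 100.0  # raw-intensity offset so that dF/F0 ~ planted waveform

#: Per-cell frequency draws are capped at 8.5 cycles/min (~0.142 Hz), just
#: inside the 0.01-0.15 Hz analysis band; faster cells would be invisible to
#: the band-passed pipeline by construction.
FREQ_CAP_CPM = 8.5
FREQ_FLOOR_CPM = 0.3


# ---------------------------------------------------------------------------
# point processes and kernels
# ---------------------------------------------------------------------------

def gamma_train(
    rng: np.random.Generator,
    rate_cpm: float,
    cv_pct: float,
    t_start: float,
    t_stop: float,
) -> np.ndarray:
    """Event times of a gamma renewal process on [t_start, t_stop).

    Interval CV (sd/mean) equals ``cv_pct``/100; shape = 1/CV^2.
    """
    if rate_cpm <= 0 or t_stop <= t_start:
        return np.empty(0)
    mean_s = 60.0 / rate_cpm
    cv = max(cv_pct, 1e-6) / 100.0
    shape = 1.0 / cv**2
    scale = mean_s / shape
    # stationary-ish start: first event a uniform fraction of one interval in
    times = []
    t = t_start + rng.uniform(0.0, 1.0) * rng.gamma(shape, scale)
    while t < t_stop:
        times.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(times)


def transient_kernel(sampling_interval_s: float,
                     rise_s: float = KERNEL_RISE_S,
                     decay_s: float = KERNEL_DECAY_S) -> tuple[np.ndarray, int]:
    """Sampled calcium-transient kernel, unit peak amplitude.

    Returns ``(kernel, i_max)`` where ``i_max`` is the index of the kernel
    maximum, so callers can align rendered traces on the transient peak.
    """
    t_end = rise_s + 6.0 * decay_s
    t = np.arange(0.0, t_end, sampling_interval_s)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    k /= k.max()
    return k, int(np.argmax(k))


def render_dff(
    peak_times_s: np.ndarray,
    peak_amplitudes: np.ndarray,
    n_samples: int,
    sampling_interval_s: float,
) -> np.ndarray:
    """dF/F0 waveform whose local maxima sit at ``peak_times_s`` (+-1 sample)."""
    dff = np.zeros(n_samples)
    if peak_times_s.size == 0:
        return dff
    kernel, i_max = transient_kernel(sampling_interval_s)
    impulses = np.zeros(n_samples + kernel.size)
    idx = np.round(np.asarray(peak_times_s) / sampling_interval_s).astype(int)
    keep = (idx >= 0) & (idx < n_samples)
    np.add.at(impulses, idx[keep] + i_max, np.asarray(peak_amplitudes)[keep])
    full = np.convolve(impulses, kernel)
    # shift so the kernel maximum lands on the deposited index
    return full[2 * i_max: 2 * i_max + n_samples]


def _draw_freq(rng: np.random.Generator, spec: PopulationSpec, size: int) -> np.ndarray:
    """Truncated-normal per-cell rates, symmetric about the mean.

    The truncation window is the largest symmetric interval around
    ``freq_mean`` that fits inside [FREQ_FLOOR, freq_max] and +-2 sd, so the
    planted population mean equals ``freq_mean`` exactly.
    """
    cap = spec.freq_max if spec.freq_max is not None else FREQ_CAP_CPM
    half = min(2.0 * spec.freq_sd, spec.freq_mean - FREQ_FLOOR_CPM, cap - spec.freq_mean)
    half = max(half, 0.0)
    lo, hi = spec.freq_mean - half, spec.freq_mean + half
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            f = rng.normal(spec.freq_mean, spec.freq_sd)
            if lo <= f <= hi:
                out[i] = f
                break
        else:
            out[i] = spec.freq_mean
    return out


# ---------------------------------------------------------------------------
# slice generation
# ---------------------------------------------------------------------------

def _epochs(protocol: StimulusProtocol, duration_s: float) -> list[tuple[float, float, float, float]]:
    """(t0, t1, astro_mult, neuron_mult) per epoch covering [0, duration)."""
    if protocol.kind == "none":
        return [(0.0, duration_s, 1.0, 1.0)]
    eps = []
    if protocol.onset_s > 0:
        eps.append((0.0, protocol.onset_s, 1.0, 1.0))
    eps.append((protocol.onset_s, min(protocol.end_s, duration_s),
                protocol.astro_freq_multiplier, protocol.neuron_freq_multiplier))
    if protocol.end_s < duration_s:
        eps.append((protocol.end_s, duration_s, 1.0, 1.0))
    return eps


def _sample_plan(rng: np.random.Generator, coupling: CouplingSpec,
                 n_astro_pool: int, n_neuron_pool: int) -> list[AssemblyPlan]:
    """Sample assembly compositions when no explicit plan is given."""
    plan: list[AssemblyPlan] = []
    a_left, n_left = n_astro_pool, n_neuron_pool
    for _ in range(coupling.n_assemblies):
        size = max(2, int(round(rng.normal(coupling.assembly_size_mean, 1.0))))
        if rng.uniform() < coupling.mixed_edge_target and a_left >= 1 and n_left >= 1:
            n_a = min(max(1, size // 3), a_left)
            n_n = min(size - n_a, n_left)
            if n_n >= 1:
                plan.append(AssemblyPlan(n_a, n_n, locked=True))
                a_left -= n_a
                n_left -= n_n
                continue
        total_left = a_left + n_left
        if total_left == 0:
            break
        if rng.uniform() < a_left / total_left and a_left >= 2:
            n_a = min(size, a_left)
            plan.append(AssemblyPlan(n_a, 0))
            a_left -= n_a
        elif n_left >= 2:
            n_n = min(size, n_left)
            plan.append(AssemblyPlan(0, n_n))
            n_left -= n_n
    return plan


def correlation_jitter_s(
    target_corr: float,
    sampling_interval_s: float = 0.5,
    band_hz: tuple[float, float] = (0.01, 0.15),
) -> float:
    """Peak-time jitter (s) that makes two jittered copies of one master
    train correlate at ``target_corr`` after band-pass filtering.

    Solved numerically from the autocorrelation of the band-passed transient
    kernel: two members whose peaks are displaced by independent N(0, σ²)
    have expected signal correlation E[ρ(Δ)] with Δ ~ N(0, 2σ²), where ρ is
    the kernel autocorrelation.
    """
    if target_corr >= 0.999:
        return 0.0
    from scipy import signal as _sg

    dt = sampling_interval_s
    kernel, _ = transient_kernel(dt)
    pad = int(round(2.0 / band_hz[0] / dt))
    padded = np.zeros(kernel.size + 2 * pad)
    padded[pad: pad + kernel.size] = kernel
    sos = _sg.butter(2, band_hz, btype="bandpass", fs=1.0 / dt, output="sos")
    kf = _sg.sosfiltfilt(sos, padded)
    acf = np.correlate(kf, kf, mode="full")
    acf = acf / acf.max()
    lags = (np.arange(acf.size) - (acf.size - 1) / 2) * dt
    sigmas = np.linspace(0.0, 10.0, 101)
    best = sigmas[-1]
    for s in sigmas:
        if s == 0.0:
            r = 1.0
        else:
            w = np.exp(-(lags**2) / (4.0 * s**2))
            r = float(np.sum(acf * w) / np.sum(w))
        if r <= target_corr:
            best = s
            break
    # the kernel-autocorrelation model understates decorrelation on renewal
    # trains (overlapping transients, grid quantisation); factor calibrated
    # against simulated member pairs at 2 Hz sampling
    return 0.6 * float(best)


def _member_peaks(
    rng: np.random.Generator,
    master: np.ndarray,
    jitter_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One member's peak times: a jittered copy of the master train.

    Copying every master event preserves the member's rate and interval CV
    exactly; the jitter controls the pairwise correlation between members.
    Returns (times, from_master) with ``from_master`` all true.
    """
    times = master.copy()
    if jitter_s > 0 and times.size:
        times = times + rng.normal(0.0, jitter_s, size=times.size)
    order = np.argsort(times)
    return times[order], np.ones(times.size, bool)[order]


def generate_slice(
    population_specs: Sequence[PopulationSpec],
    coupling: Optional[CouplingSpec] = None,
    protocol: Optional[StimulusProtocol] = None,
    duration_s: float = 300.0,
    seed: int = 0,
    sampling_interval_s: float = 0.5,
    region: str = "",
    slice_id: str = "",
) -> SliceRecording:
    """Generate one synthetic slice recording.

    Active cells oscillate at a rate drawn from their population's
    (freq_mean, freq_sd); inactive cells are noise-only.  Cells within an
    assembly share peak times up to the coupling jitter; mixed assemblies
    phase-lock astrocyte peaks to a subset of the neuron master events.
    Identical seed and parameters produce identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    protocol = protocol or StimulusProtocol()
    coupling = coupling or CouplingSpec()
    if protocol.kind != "none" and protocol.end_s > duration_s + 1e-9:
        raise ValueError("protocol epochs exceed recording duration")

    rng = np.random.default_rng(seed)
    dt = sampling_interval_s
    n_samples = int(round(duration_s / dt))
    epochs = _epochs(protocol, duration_s)
    epoch_spans = [(t0, t1) for (t0, t1, _, _) in epochs]

    pop_by_label = {p.label: p for p in population_specs}
    labels: list[str] = []
    active = []
    for spec in population_specs:
        labels.extend([spec.label] * spec.n_cells)
        flags = np.zeros(spec.n_cells, bool)
        n_active = int(round(spec.n_cells * spec.frac_active))
        flags[rng.choice(spec.n_cells, size=n_active, replace=False)] = True
        active.append(flags)
    labels_arr = np.asarray(labels)
    active_arr = np.concatenate(active) if active else np.zeros(0, bool)
    n_cells = labels_arr.size

    astro_pool = list(np.flatnonzero((labels_arr == ASTROCYTE) & active_arr))
    neuron_pool = list(np.flatnonzero((labels_arr == NEURON) & active_arr))
    rng.shuffle(astro_pool)
    rng.shuffle(neuron_pool)

    plan = coupling.assembly_plan
    if plan is None:
        plan = _sample_plan(rng, coupling, len(astro_pool), len(neuron_pool))

    member_jitter = correlation_jitter_s(coupling.within_assembly_corr,
                                         sampling_interval_s)
    k_lock = coupling.astro_neuron_lock_ratio

    peak_times: list[np.ndarray] = [np.empty(0)] * n_cells
    burst_flags: list[np.ndarray] = [np.empty(0, bool)] * n_cells
    planted_freq = np.zeros(n_cells)
    assembly_id = np.full(n_cells, -1)
    locked_flag = np.zeros(n_cells, bool)
    assembly_of: dict[int, int] = {}

    astro_spec = pop_by_label.get(ASTROCYTE)
    neuron_spec = pop_by_label.get(NEURON)

    def pop_mult(label: str, ep: tuple[float, float, float, float]) -> float:
        return ep[2] if label == ASTROCYTE else ep[3]

    # --- assemblies -------------------------------------------------------
    for a_idx, ap in enumerate(plan):
        members_a = [astro_pool.pop() for _ in range(min(ap.n_astro, len(astro_pool)))]
        members_n = [neuron_pool.pop() for _ in range(min(ap.n_neuron, len(neuron_pool)))]
        if not members_a and not members_n:
            continue
        # master rate comes from the dominant population of the assembly
        if members_n:
            master_spec = neuron_spec
        else:
            master_spec = astro_spec
        master_rate = float(_draw_freq(rng, master_spec, 1)[0])

        # neuron (or pure-astro) master train per epoch
        master_parts = []
        for ep in epochs:
            t0, t1, _, _ = ep
            master_parts.append(
                gamma_train(rng, master_rate * pop_mult(master_spec.label, ep),
                            master_spec.ipi_cv, t0, t1))
        master = np.concatenate(master_parts)

        # astro master: every k-th master event (strict subset) when the
        # assembly is mixed+locked; under unequal stimulus multipliers the
        # astrocytes are driven directly and decouple for that epoch.
        astro_master = None
        astro_master_in_master = None
        if members_a and members_n and ap.locked:
            parts = []
            flags = []
            offset = int(rng.integers(0, k_lock))
            for ep, mpart in zip(epochs, master_parts):
                t0, t1, ma, mn = ep
                if math.isclose(ma, mn):
                    sel = mpart[offset::k_lock]
                    if coupling.lock_jitter > 0 and sel.size:
                        sel = sel + rng.normal(0.0, coupling.lock_jitter,
                                               size=sel.size)
                    parts.append(sel)
                    flags.append(np.ones(sel.size, bool))
                else:
                    # unequal stimulus drive decouples the lock: astrocytes
                    # are driven directly at their own multiplied rate
                    rate = master_rate / k_lock * ma
                    ind = gamma_train(rng, rate, master_spec.ipi_cv, t0, t1)
                    parts.append(ind)
                    flags.append(np.zeros(ind.size, bool))
            astro_master = np.concatenate(parts)
            astro_master_in_master = np.concatenate(flags)

        for i in members_n:
            t, from_master = _member_peaks(rng, master, member_jitter)
            peak_times[i] = t
            # a member peak "bursts" (higher amplitude) if it copies a master
            # event that the astro master also carries — phase-locked network
            # events are the large, coordinated ones
            burst = np.zeros(t.size, bool)
            if astro_master is not None and astro_master_in_master.any() and t.size:
                locked_times = astro_master[astro_master_in_master]
                tol = 3.0 * (member_jitter + coupling.lock_jitter) + 1e-9
                for j in np.flatnonzero(from_master):
                    if np.min(np.abs(locked_times - t[j])) <= tol:
                        burst[j] = True
            burst_flags[i] = burst
            planted_freq[i] = master_rate
            assembly_id[i] = a_idx

        for i in members_a:
            if astro_master is not None:
                base = astro_master
                rate = master_rate / k_lock
                locked_flag[i] = True
            else:
                base = master
                rate = master_rate
            t, _ = _member_peaks(rng, base, member_jitter)
            peak_times[i] = t
            burst_flags[i] = np.zeros(t.size, bool)
            planted_freq[i] = rate
            assembly_id[i] = a_idx

    # --- independent active cells ----------------------------------------
    for label, pool in ((ASTROCYTE, astro_pool), (NEURON, neuron_pool)):
        spec = pop_by_label.get(label)
        if spec is None:
            continue
        for i in pool:
            rate = float(_draw_freq(rng, spec, 1)[0])
            parts = [gamma_train(rng, rate * pop_mult(label, ep), spec.ipi_cv,
                                 ep[0], ep[1]) for ep in epochs]
            peak_times[i] = np.concatenate(parts)
            burst_flags[i] = np.zeros(peak_times[i].size, bool)
            planted_freq[i] = rate

    # --- inactive-astrocyte FLRF transient --------------------------------
    if (protocol.kind == "flrf" and protocol.inactive_transient
            and protocol.genotype == GENOTYPE_MRGA1):
        for i in np.flatnonzero((labels_arr == ASTROCYTE) & ~active_arr):
            t = protocol.onset_s + rng.uniform(0.0, protocol.transient_return_s)
            peak_times[i] = np.array([t])
            burst_flags[i] = np.zeros(1, bool)

    # --- positions --------------------------------------------------------
    positions = rng.uniform(0.0, FIELD_UM, size=(n_cells, 2))
    margin = ASSEMBLY_RADIUS_UM
    for a_idx in range(len(plan)):
        members = np.flatnonzero(assembly_id == a_idx)
        if members.size == 0:
            continue
        center = rng.uniform(margin, FIELD_UM - margin, size=2)
        r = ASSEMBLY_RADIUS_UM * np.sqrt(rng.uniform(size=members.size))
        theta = rng.uniform(0.0, 2 * np.pi, size=members.size)
        positions[members, 0] = center[0] + r * np.cos(theta)
        positions[members, 1] = center[1] + r * np.sin(theta)

    # --- render traces ----------------------------------------------------
    traces = []
    amplitudes = np.zeros(n_cells)
    final_peaks: list[np.ndarray] = []
    for i in range(n_cells):
        spec = pop_by_label[labels_arr[i]]
        amp = max(0.05, rng.normal(spec.amplitude_mean, spec.amplitude_sd))
        amplitudes[i] = amp
        t = peak_times[i]
        keep = (t >= 0) & (t < duration_s)
        t = t[keep]
        bursts = burst_flags[i][keep] if burst_flags[i].size else np.zeros(0, bool)
        order = np.argsort(t)
        t, bursts = t[order], bursts[order]
        peak_amp = amp * rng.uniform(0.85, 1.15, size=t.size)
        if bursts.size:
            peak_amp = peak_amp * np.where(bursts, 1.0 + coupling.burst_boost, 1.0)
        dff = render_dff(t, peak_amp, n_samples, dt)
        noise = rng.normal(0.0, spec.noise_sd, size=n_samples) if spec.noise_sd > 0 else 0.0
        raw = BASELINE_OFFSET * (1.0 + dff + noise)
        cid = f"cell{i:04d}"
        traces.append(FluorescenceTrace(raw, dt, cid))
        final_peaks.append(t)

    truth = GroundTruth(
        active=active_arr,
        frequency_cpm=np.where(active_arr, planted_freq, 0.0),
        assembly_id=assembly_id,
        locked=locked_flag,
        amplitude=amplitudes,
        peak_times_s=final_peaks,
    )
    return SliceRecording(
        region=region,
        traces=traces,
        positions=positions,
        gfap_positive=(labels_arr == ASTROCYTE),
        protocol=protocol,
        sampling_interval_s=dt,
        ground_truth=truth,
        slice_id=slice_id,
    )


# ---------------------------------------------------------------------------
# published-study presets
# ---------------------------------------------------------------------------

PRESET_CONDITIONS = ("control", "flrf", "wt_flrf", "hypercapnia", "flrf_then_hypercapnia")

#: Hypercapnic rate gain of the naive pFRG/RTN network.  The study reports a
#: frequency response but prints no fold value, only that pre-activation
#: blunts it; the default gain of 2 is a free parameter of the model.
HYPERCAPNIA_GAIN = 2.0


def _pfrg_populations() -> list[PopulationSpec]:
    # 70% astrocytes; 18% of astrocytes active; astro share of active cells 40%
    return [
        PopulationSpec(ASTROCYTE, n_cells=210, frac_active=0.18,
                       freq_mean=1.1, freq_sd=0.4, ipi_cv=33.0),
        PopulationSpec(NEURON, n_cells=90, frac_active=0.63,
                       freq_mean=6.4, freq_sd=3.5, ipi_cv=33.0),
    ]


def _prebotc_populations() -> list[PopulationSpec]:
    # 61% astrocytes; 13% of astrocytes active; astro share of active cells 20%
    return [
        PopulationSpec(ASTROCYTE, n_cells=183, frac_active=0.13,
                       freq_mean=1.1, freq_sd=0.5, ipi_cv=35.0),
        PopulationSpec(NEURON, n_cells=117, frac_active=0.82,
                       freq_mean=5.4, freq_sd=2.4, ipi_cv=35.0),
    ]


def _pfrg_coupling() -> CouplingSpec:
    # Planted edge counts: astro-astro 85, neuron-neuron 76, mixed 75
    # -> 36/32/32% of correlating pairs; astro clusters mean 5.43,
    # neuron clusters mean 4.875.
    plan = [
        AssemblyPlan(6, 5, locked=True),
        AssemblyPlan(5, 5, locked=True),
        AssemblyPlan(5, 4, locked=True),
        AssemblyPlan(6, 0), AssemblyPlan(6, 0),
        AssemblyPlan(5, 0), AssemblyPlan(5, 0),
        AssemblyPlan(0, 5), AssemblyPlan(0, 5), AssemblyPlan(0, 5),
        AssemblyPlan(0, 5), AssemblyPlan(0, 5),
    ]
    return CouplingSpec(assembly_plan=plan, within_assembly_corr=0.8,
                        astro_neuron_lock_ratio=6, lock_jitter=0.5)


def _prebotc_coupling() -> CouplingSpec:
    # Planted edge counts: astro-astro 60, neuron-neuron 225, mixed 90
    # -> exactly 16/24/60% of correlating pairs; neuron clusters mean 5.81,
    # astro clusters 6.0.
    plan = (
        [AssemblyPlan(6, 5, locked=True)] * 3
        + [AssemblyPlan(6, 0)]
        + [AssemblyPlan(0, 6)] * 13
    )
    return CouplingSpec(assembly_plan=plan, within_assembly_corr=0.8,
                        astro_neuron_lock_ratio=5, lock_jitter=0.5)


def paper_preset(
    region: str,
    condition: str = "control",
    onset_s: float = 300.0,
    stimulus_duration_s: float = 300.0,
) -> tuple[list[PopulationSpec], CouplingSpec, StimulusProtocol]:
    """Population, coupling and protocol specs matching the published study.

    Regions: ``pFRG/RTN`` or ``preBotC`` (``preBötC`` accepted).  Conditions:
    control, flrf, wt_flrf, hypercapnia, flrf_then_hypercapnia.  FLRF triples
    the astrocytic rate in both regions and doubles the neuronal rate in the
    pFRG/RTN only; WT slices do not respond; pre-activated (post-FLRF) slices
    show a blunted (unit-gain) hypercapnic response, and the preBötC does not
    respond to hypercapnia at all.
    """
    region_norm = region.replace("ö", "o").replace("Ö", "O")
    if region_norm not in (REGION_PFRG, REGION_PREBOTC):
        raise ValueError(f"unknown region {region!r}")
    if condition not in PRESET_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")

    if region_norm == REGION_PFRG:
        pops = _pfrg_populations()
        coupling = _pfrg_coupling()
        flrf_neuron_mult = 2.0
        hypercapnia_mult = HYPERCAPNIA_GAIN
    else:
        pops = _prebotc_populations()
        coupling = _prebotc_coupling()
        flrf_neuron_mult = 1.0
        hypercapnia_mult = 1.0

    if condition == "control":
        protocol = StimulusProtocol(kind="none")
    elif condition in ("flrf", "wt_flrf"):
        protocol = StimulusProtocol(
            kind="flrf", onset_s=onset_s, duration_s=stimulus_duration_s,
            astro_freq_multiplier=3.0, neuron_freq_multiplier=flrf_neuron_mult,
            inactive_transient=True, transient_return_s=10.0,
            genotype=GENOTYPE_WT if condition == "wt_flrf" else GENOTYPE_MRGA1)
    elif condition == "hypercapnia":
        protocol = StimulusProtocol(
            kind="hypercapnia", onset_s=onset_s, duration_s=stimulus_duration_s,
            astro_freq_multiplier=hypercapnia_mult,
            neuron_freq_multiplier=hypercapnia_mult)
    else:  # flrf_then_hypercapnia: pre-activated, blunted response
        protocol = StimulusProtocol(
            kind="hypercapnia", onset_s=onset_s, duration_s=stimulus_duration_s,
            astro_freq_multiplier=1.0, neuron_freq_multiplier=1.0)
    return pops, coupling, protocol


def generate_preset_slice(
    region: str,
    condition: str = "control",
    seed: int = 0,
    duration_s: Optional[float] = None,
) -> SliceRecording:
    """Convenience wrapper: preset specs -> one slice recording."""
    pops, coupling, protocol = paper_preset(region, condition)
    if duration_s is None:
        duration_s = 300.0 if protocol.kind == "none" else protocol.end_s
    return generate_slice(pops, coupling, protocol, duration_s=duration_s,
                          seed=seed, region=region,
                          slice_id=f"{region}-{condition}-s{seed}")


# ---------------------------------------------------------------------------
# IHC image stacks
# ---------------------------------------------------------------------------

IHC_CHANNEL_A = "GFP"
IHC_CHANNEL_B = "S100B"


def ihc_paper_preset() -> dict:
    """Per-stack IHC parameters matching the published quantification.

    271 GFP cells and 31 S100β cells per stack (409 S100β / 3527 GFP cells
    over 13 stacks), 92% planted double-labeling, antibody penetration 24%
    of a 54 µm stack.
    """
    return dict(n_cells_per_channel=(271, 31), overlap_fraction=0.92,
                penetration_fraction=0.24, stack_depth_um=54.0)


def generate_ihc_stack(
    n_cells_per_channel: tuple[int, int] | int,
    overlap_fraction: float,
    penetration_fraction: float,
    stack_depth_um: float = 54.0,
    seed: int = 0,
    field_px: tuple[int, int] = (192, 192),
    voxel_size_um: tuple[float, float, float] = (2.0, 1.0, 1.0),
    cell_radius_um: float = 4.0,
    noise_sd: float = 0.02,
    shading: float = 0.15,
) -> LabeledImageStack:
    """Two-channel z-stack with planted ROIs and known double-labeling.

    Channel A (GFP, genetically encoded) spans the full slice depth; channel
    B (the antibody-stained marker) is restricted to the top
    ``penetration_fraction`` of the depth, emulating limited antibody
    penetration.  Each B ROI overlaps an A ROI with probability
    ``overlap_fraction``; planted ground truth is recorded per ROI.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if not 0.0 < penetration_fraction <= 1.0:
        raise ValueError("penetration_fraction must be in (0, 1]")
    if isinstance(n_cells_per_channel, int):
        n_a = n_b = n_cells_per_channel
    else:
        n_a, n_b = n_cells_per_channel

    rng = np.random.default_rng(seed)
    vz, vy, vx = voxel_size_um
    nz = int(round(stack_depth_um / vz))
    ny, nx = field_px
    r_xy = cell_radius_um / vy
    r_z = cell_radius_um / vz
    if 2 * r_xy >= min(ny, nx) or r_z >= nz:
        raise ValueError("cell radius too large for the field geometry")

    def too_close(c, others, min_sep_factor=2.2):
        # anisotropy-scaled center distance within a channel
        if not others:
            return False
        arr = np.asarray(others)
        d = np.sqrt(((arr[:, 0] - c[0]) * vz) ** 2
                    + ((arr[:, 1] - c[1]) * vy) ** 2
                    + ((arr[:, 2] - c[2]) * vx) ** 2)
        return bool(np.min(d) < min_sep_factor * cell_radius_um)

    # --- place channel A over the full depth ------------------------------
    # cells may clip at the antibody-entry (z=0) face, as in a real slice
    a_centers: list[tuple[float, float, float]] = []
    for _ in range(n_a):
        for _try in range(4000):
            c = (rng.uniform(0.4, nz - r_z),
                 rng.uniform(r_xy, ny - r_xy),
                 rng.uniform(r_xy, nx - r_xy))
            if not too_close(c, a_centers):
                a_centers.append(c)
                break
        else:
            raise ValueError("could not place channel-A ROIs; field too crowded")

    # --- place channel B within the penetrated depth ----------------------
    z_max_b = penetration_fraction * nz
    a_arr = np.asarray(a_centers)
    top_a = np.flatnonzero(a_arr[:, 0] <= max(z_max_b - 0.3, 0.5)) if n_a else np.array([], int)
    b_centers: list[tuple[float, float, float]] = []
    b_overlaps: list[bool] = []
    for _ in range(n_b):
        wants_overlap = bool(rng.uniform() < overlap_fraction)
        placed = False
        if wants_overlap and top_a.size:
            for _try in range(2000):
                host = a_centers[int(rng.choice(top_a))]
                # offset well inside the host so masks share voxels robustly
                off = rng.normal(0.0, 0.15 * cell_radius_um, size=3)
                c = (min(max(host[0] + off[0] / vz, 0.0), z_max_b),
                     min(max(host[1] + off[1] / vy, r_xy), ny - r_xy),
                     min(max(host[2] + off[2] / vx, r_xy), nx - r_xy))
                if not too_close(c, b_centers):
                    b_centers.append(c)
                    b_overlaps.append(True)
                    placed = True
                    break
        if not placed:
            for _try in range(4000):
                c = (rng.uniform(0.2, z_max_b),
                     rng.uniform(r_xy, ny - r_xy),
                     rng.uniform(r_xy, nx - r_xy))
                if too_close(c, b_centers):
                    continue
                if n_a and too_close(c, a_centers, min_sep_factor=2.6):
                    continue
                b_centers.append(c)
                b_overlaps.append(False)
                placed = True
                break
        if not placed:
            raise ValueError("could not place channel-B ROIs; field too crowded")

    # --- render ------------------------------------------------------------
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]

    def render(centers: list[tuple[float, float, float]]) -> np.ndarray:
        vol = np.zeros((nz, ny, nx))
        for (cz, cy, cx) in centers:
            amp = rng.uniform(0.8, 1.2)
            z0, z1 = max(0, int(cz - r_z) - 1), min(nz, int(cz + r_z) + 2)
            y0, y1 = max(0, int(cy - r_xy) - 1), min(ny, int(cy + r_xy) + 2)
            x0, x1 = max(0, int(cx - r_xy) - 1), min(nx, int(cx + r_xy) + 2)
            dz = (zz[z0:z1] - cz) / r_z
            dy = (yy[:, y0:y1] - cy) / r_xy
            dx = (xx[:, :, x0:x1] - cx) / r_xy
            rho2 = dz**2 + dy**2 + dx**2
            vol[z0:z1, y0:y1, x0:x1] += amp * np.clip(1.2 - rho2, 0.0, 1.0) / 1.2
        # mild shading gradient across x plus depth attenuation
        bg = shading * (xx / nx) + 0.5 * shading * (zz / nz)
        vol = vol + bg
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
        return np.clip(vol, 0.0, None)

    radius = (r_z, r_xy, r_xy)
    planted = {
        IHC_CHANNEL_A: [PlantedRoi(IHC_CHANNEL_A, c, radius) for c in a_centers],
        IHC_CHANNEL_B: [PlantedRoi(IHC_CHANNEL_B, c, radius, ov)
                        for c, ov in zip(b_centers, b_overlaps)],
    }
    channels = {IHC_CHANNEL_A: render(a_centers), IHC_CHANNEL_B: render(b_centers)}
    return LabeledImageStack(
        channels=channels, voxel_size_um=voxel_size_um, planted_rois=planted,
        planted_overlap_fraction=overlap_fraction,
        penetration_fraction=penetration_fraction, stack_id=f"stack-s{seed}")


def planted_mask(roi: PlantedRoi, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean voxel mask of a planted ROI (brute-force oracle geometry)."""
    nz, ny, nx = shape
    cz, cy, cx = roi.center_zyx
    rz, ry, rx = roi.radius_zyx
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    rho2 = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    return rho2 <= 1.2  # matches the rendered support (clip at rho2 = 1.2)


# ---------------------------------------------------------------------------
# PGE2 timecourse
# ---------------------------------------------------------------------------

def generate_pge2(
    baseline_level: float = 10.0,
    fold_change: float = 2.0,
    onset_min: float = 10.0,
    transient_width_min: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    total_min: float = 30.0,
) -> Pge2Timecourse:
    """Perfusate PGE2 concentration sampled each minute.

    The response is a raised-cosine transient peaking at
    ``baseline_level * fold_change`` halfway through ``transient_width_min``
    and returning to baseline by its end.
    """
    if baseline_level <= 0:
        raise ValueError("baseline_level must be positive")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_min + 0.5, 1.0)
    conc = np.full(t.size, float(baseline_level))
    in_pulse = (t >= onset_min) & (t <= onset_min + transient_width_min)
    phase = (t[in_pulse] - onset_min) / transient_width_min
    conc[in_pulse] += baseline_level * (fold_change - 1.0) * 0.5 * (
        1.0 - np.cos(2 * np.pi * phase))
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=conc.size)
    return Pge2Timecourse(times_min=t, concentration=np.clip(conc, 0.0, None),
                          stimulus_onset_min=onset_min)
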