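"""Domain types shared across the pipeline.

The atomic input is a single cell's fluorescence time series; the unit of
analysis is a :class:`SliceRecording` — all cells of one organotypic brainstem
slice culture, with positions, GFAP labels (GFAP+ = astrocyte), the stimulus
protocol, and (for synthetic slices) the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_SAMPLING_INTERVAL_S = 0.5

ASTROCYTE = "astrocyte"
NEURON = "neuron"

REGION_PFRG = "pFRG/RTN"
REGION_PREBOTC = "preBotC"

GENOTYPE_MRGA1 = "GFAPMrgA1"
GENOTYPE_WT = "WT"


class UnusableTraceError(ValueError):
    """Raised when a trace cannot be normalised (e.g. non-positive baseline)."""


@dataclass
class FluorescenceTrace:
    """One cell's raw intensity series (arbitrary units)."""

    values: np.ndarray
    sampling_interval_s: float = DEFAULT_SAMPLING_INTERVAL_S
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval_s


@dataclass
class DffTrace:
    """A ΔF/F₀ series, optionally band-pass filtered.

    ``noise_scale`` is a robust estimate of the additive noise standard
    deviation obtained from the *unfiltered* ΔF/F₀ series; it is carried
    through filtering so peak detection can threshold prominences against
    the true noise floor rather than the (much smoother) filtered trace.
    """

    values: np.ndarray
    f0: float
    sampling_interval_s: float = DEFAULT_SAMPLING_INTERVAL_S
    cell_id: str = ""
    filtered: bool = False
    band_hz: Optional[tuple[float, float]] = None
    noise_scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.f0 <= 0:
            raise UnusableTraceError(f"baseline F0 must be positive, got {self.f0}")
        if self.band_hz is not None:
            low, high = self.band_hz
            nyquist = 0.5 / self.sampling_interval_s
            if not (0 < low < high < nyquist):
                raise ValueError(
                    f"band edges must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
                )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval_s


@dataclass
class OscillationStats:
    """Detected peaks and derived oscillation statistics for one cell."""

    cell_id: str
    peak_times_s: np.ndarray
    trace_duration_s: float
    frequency_cpm: Optional[float] = None
    ipi_cv_pct: Optional[float] = None
    active: Optional[bool] = None

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)

    @property
    def n_peaks(self) -> int:
        return self.peak_times_s.size


@dataclass
class PopulationSpec:
    """Parameters of one cell population (astrocytes or neurons) in a slice."""

    label: str
    n_cells: int
    frac_active: float
    freq_mean: float  # cycles/min
    freq_sd: float  # cycles/min
    amplitude_mean: float = 0.45  # ΔF/F₀ peak amplitude
    amplitude_sd: float = 0.10
    ipi_cv: float = 33.0  # percent
    noise_sd: float = 0.015  # ΔF/F₀ units
    freq_max: Optional[float] = None  # truncation cap (cycles/min)

    def __post_init__(self) -> None:
        if self.label not in (ASTROCYTE, NEURON):
            raise ValueError(f"unknown population label {self.label!r}")
        if not 0.0 <= self.frac_active <= 1.0:
            raise ValueError("frac_active must be in [0, 1]")
        if self.freq_mean <= 0:
            raise ValueError("freq_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


@dataclass
class AssemblyPlan:
    """Explicit composition of one correlated cell assembly."""

    n_astro: int = 0
    n_neuron: int = 0
    locked: bool = False  # astro members phase-locked to the neuron master

    @property
    def size(self) -> int:
        return self.n_astro + self.n_neuron


@dataclass
class CouplingSpec:
    """How active cells are organised into correlated assemblies.

    If ``assembly_plan`` is given it fully determines assembly compositions;
    otherwise ``n_assemblies``/``assembly_size_mean``/``mixed_edge_target``
    are used to sample a plan.
    """

    n_assemblies: int = 0
    assembly_size_mean: float = 6.0
    within_assembly_corr: float = 0.8
    astro_neuron_lock_ratio: int = 2
    lock_jitter: float = 0.5  # s
    mixed_edge_target: float = 0.0
    assembly_plan: Optional[list[AssemblyPlan]] = None
    burst_boost: float = 0.75  # amplitude gain of neuron events locked to astro peaks

    def __post_init__(self) -> None:
        if self.n_assemblies < 0:
            raise ValueError("n_assemblies must be non-negative")
        if not 0.0 <= self.within_assembly_corr <= 1.0:
            raise ValueError("within_assembly_corr must be in [0, 1]")
        if self.astro_neuron_lock_ratio < 1:
            raise ValueError("astro_neuron_lock_ratio must be >= 1")


@dataclass
class StimulusProtocol:
    """Timing and effect sizes of the applied stimulus.

    ``kind='flrf'`` models bath application of the MrgA1R agonist peptide;
    ``kind='hypercapnia'`` models a CO₂ partial-pressure step (4.6 → 6.6 kPa).
    A WT genotype does not express MrgA1R, so FLRF multipliers are forced to 1
    and the inactive-astrocyte transient is suppressed.
    """

    kind: str = "none"  # none | flrf | hypercapnia
    onset_s: float = 0.0
    duration_s: float = 0.0
    astro_freq_multiplier: float = 1.0
    neuron_freq_multiplier: float = 1.0
    inactive_transient: bool = False
    transient_return_s: float = 10.0
    genotype: str = GENOTYPE_MRGA1

    def __post_init__(self) -> None:
        if self.kind not in ("none", "flrf", "hypercapnia"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.astro_freq_multiplier <= 0 or self.neuron_freq_multiplier <= 0:
            raise ValueError("frequency multipliers must be positive")
        if self.genotype not in (GENOTYPE_MRGA1, GENOTYPE_WT):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.genotype == GENOTYPE_WT and self.kind == "flrf":
            # WT slices do not express MrgA1R and do not react to FLRF.
            self.astro_freq_multiplier = 1.0
            self.neuron_freq_multiplier = 1.0
            self.inactive_transient = False

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def control_epoch(self, recording_duration_s: float) -> tuple[float, float]:
        if self.kind == "none":
            return (0.0, recording_duration_s)
        return (0.0, self.onset_s)

    def stimulus_epoch(self) -> tuple[float, float]:
        if self.kind == "none":
            raise ValueError("protocol has no stimulus epoch")
        return (self.onset_s, self.end_s)


@dataclass
class GroundTruth:
    """Planted per-cell truth recorded by the synthetic generator."""

    active: np.ndarray  # bool, per cell
    frequency_cpm: np.ndarray  # planted control-epoch rate; 0 for inactive
    assembly_id: np.ndarray  # int, -1 = not in an assembly
    locked: np.ndarray  # bool, astro phase-locked to a neuron master
    amplitude: np.ndarray
    peak_times_s: list[np.ndarray] = field(default_factory=list)

    def n_cells(self) -> int:
        return self.active.size


@dataclass
class SliceRecording:
    """All traces of one slice plus positions, labels, protocol and truth."""

    region: str
    traces: list[FluorescenceTrace]
    positions: np.ndarray  # (n, 2) µm
    gfap_positive: np.ndarray  # (n,) bool
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    sampling_interval_s: float = DEFAULT_SAMPLING_INTERVAL_S
    ground_truth: Optional[GroundTruth] = None
    slice_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.gfap_positive = np.asarray(self.gfap_positive, dtype=bool)
        n = len(self.traces)
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_cells, 2)")
        if self.gfap_positive.shape != (n,):
            raise ValueError("gfap_positive must have one flag per cell")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        lengths = {t.n_samples for t in self.traces}
        if len(lengths) > 1:
            raise ValueError("all traces must have the same length")
        intervals = {t.sampling_interval_s for t in self.traces}
        if len(intervals) > 1:
            raise ValueError("all traces must share one sampling interval")
        if self.ground_truth is not None and self.ground_truth.n_cells() != n:
            raise ValueError("ground truth must cover every cell")

    @property
    def n_cells(self) -> int:
        return len(self.traces)

    @property
    def n_samples(self) -> int:
        return self.traces[0].n_samples if self.traces else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval_s

    @property
    def cell_ids(self) -> list[str]:
        return [t.cell_id for t in self.traces]

    def values_matrix(self) -> np.ndarray:
        """Raw intensities as an (n_cells, n_samples) array."""
        return np.vstack([t.values for t in self.traces])


@dataclass
class Roi:
    """One detected (or planted) region of interest in an image stack."""

    roi_id: int
    channel: str
    area_px: int
    centroid_zyx: tuple[float, float, float]


@dataclass
class RoiSet:
    """ROIs of one channel plus the label volume they index into."""

    channel: str
    rois: list[Roi]
    label_volume: np.ndarray  # int labels; 0 = background
    min_area_px: int
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __len__(self) -> int:
        return len(self.rois)

    def centroid_depths_um(self) -> np.ndarray:
        """Centroid depth of each ROI in µm from the antibody-entry (z=0) face."""
        return np.array([r.centroid_zyx[0] * self.voxel_size_um[0] for r in self.rois])


@dataclass
class ColocalizationReport:
    """Cross-channel double-labeling counts and fractions (percent)."""

    n_a: int
    n_b: int
    double_labeled: int
    fraction_a_also_b: float
    fraction_b_also_a: float
    depth_restricted: bool = False
    depth_range_um: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.double_labeled > min(self.n_a, self.n_b):
            raise ValueError("double-labeled count cannot exceed either channel count")


@dataclass
class PlantedRoi:
    channel: str
    center_zyx: tuple[float, float, float]
    radius_zyx: tuple[float, float, float]
    overlaps_partner: bool = False


@dataclass
class LabeledImageStack:
    """Synthetic two-channel 3-D image with planted ground-truth ROIs."""

    channels: dict[str, np.ndarray]  # name -> (z, y, x)
    voxel_size_um: tuple[float, float, float]
    planted_rois: dict[str, list[PlantedRoi]]
    planted_overlap_fraction: float
    penetration_fraction: float
    stack_id: str = ""

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must have identical shapes")
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise ValueError("planted_overlap_fraction must be in [0, 1]")
        if not 0.0 < self.penetration_fraction <= 1.0:
            raise ValueError("penetration_fraction must be in (0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def stack_depth_um(self) -> float:
        return self.shape[0] * self.voxel_size_um[0]


@dataclass
class Pge2Timecourse:
    """PGE2 concentration in the perfusate, sampled each minute."""

    times_min: np.ndarray
    concentration: np.ndarray
    stimulus_onset_min: float

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")


def cell_labels(recording: SliceRecording) -> np.ndarray:
    """Per-cell type labels derived from the GFAP flag."""
    return np.where(recording.gfap_positive, ASTROCYTE, NEURON)
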