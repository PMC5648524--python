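# Methods

This note describes the models and numerical choices behind `caslice`: what
the synthetic-slice generator simulates and why, how each analysis stage is
parameterised, and where the pipeline's physical limits are.

## The synthetic slice model

A slice recording is a set of per-cell raw-intensity traces sampled every
0.5 s, with cell positions (µm), GFAP labels, a stimulus protocol and a
planted ground-truth record. Traces are built in three layers.

**Point process.** Each active cell emits calcium events as a gamma renewal
process: inter-event intervals are gamma distributed with mean 60/f s for a
rate of f cycles/min and shape 1/CV², giving direct control of the interval
CV that the pipeline must recover. Inactive cells emit no events and carry
only noise — the majority of astrocytes in these cultures are dormant.

**Transient kernel.** Events are rendered as fast-rise/exponential-decay
waveforms, K(t) = (1 − e^(−t/τ_r))·e^(−t/τ_d) with τ_r = 1 s and
τ_d = 1.5 s, unit-normalised and aligned so the kernel maximum sits on the
event time. The decay is at the fast end of somatic dye transients; a
slower default (≈ 4 s) was tried first and rejected because, after the
0.01–0.15 Hz analysis band-pass, it leaves no resolvable dip between events
less than ~6 s apart and biases neuronal rate recovery by up to −40% (see
*Calibration* below).

**Raw intensity.** F(t) = 100·(1 + ΔF/F₀(t) + ε(t)) with white noise
ε ~ N(0, 0.015). Event amplitudes are per-cell N(0.45, 0.10) ΔF/F₀ with
±15% per-event variation. The implied SNR (~30) describes clean slice
imaging; it is a stated study condition (see *Calibration*).

**Assemblies.** Correlated sub-populations are planted as assemblies: a
master event train is drawn for each assembly, and every member carries a
jittered copy of it, which preserves each member's rate and interval CV
exactly. The jitter that yields a target pairwise correlation is obtained
by numerically inverting the band-passed kernel autocorrelation, with a
0.6 correction factor calibrated on simulated member pairs (the
autocorrelation model understates decorrelation on renewal trains). At the
default target of 0.8 the realised member correlation is ≈ 0.8. Assembly
members are placed within a 150 µm radius of a random centre in a
1000 × 1000 µm field; other cells are uniform.

**Astrocyte–neuron locking.** In a mixed assembly the astrocytic master is
every k-th event of the neuronal master (k = `astro_neuron_lock_ratio`), so
every astrocytic peak coincides with a neuronal peak and the astrocytic
rate is the neuronal rate divided by k. Study presets set k to the rounded
rate ratio (5 in the preBötC, 6 in the pFRG/RTN), which reproduces the
observed ~1.1 cycles/min astrocytic rhythm locked into a ~5–6.5 cycles/min
neuronal one. Neuronal events that carry the lock are rendered 1.75× larger
(a "network burst" factor of 0.75): coordinated events are the large ones,
and this keeps locked astrocyte–neuron pairs (zero-lag r ≈ 0.5) robustly
above the surrogate cut-off, as they evidently were in the source data.
Under stimulus epochs whose astrocytic and neuronal multipliers differ, the
lock is released and astrocytes are driven directly at their own multiplied
rate.

**Study presets.** `paper_preset(region, condition)` returns population,
coupling and protocol specs whose parameters equal the published means:
cell-type proportions (70% astrocytes in the pFRG/RTN, 61% in the preBötC),
active fractions (18% / 13% of astrocytes; neuron active fractions set so
astrocytes are 40% / 20% of active cells), rates (astrocytes 1.1 ± 0.4–0.5,
neurons 6.4 ± 3.5 and 5.4 ± 2.4 cycles/min), interval CVs (33 / 35%), and
explicit assembly composition lists derived from the published cluster
sizes and edge-type shares (e.g. preBötC: 13 neuronal assemblies of 6 and 3
of 5, 4 astrocytic assemblies of 6, three of them locked — planting exactly
16% astro-astro, 24% mixed, 60% neuron-neuron pairs and a mean neuronal
cluster of 5.81 cells). Per-cell rates are truncated normals, symmetric
about the mean (so the planted mean is exact) and capped at 8.5 cycles/min
≈ the 0.142 Hz edge of the analysis band — faster cells would be invisible
to the band-passed pipeline by construction.

Stimulus conditions: FLRF (MrgA1R agonist) triples the astrocytic rate in
both regions, doubles the neuronal rate in the pFRG/RTN only, and evokes in
each inactive astrocyte a single transient within 10 s of onset; WT slices
(no MrgA1R) do not respond. Hypercapnia multiplies the naive pFRG/RTN rates
by 2 — the published account is qualitative here, so the gain is a free
parameter with default 2 — and by 1 after FLRF pre-activation (the blunted
response); the preBötC does not respond. PGE2 timecourses are a raised
cosine transient peaking at baseline × fold (default 2) and returning to
baseline within the transient width.

**IHC stacks.** Two-channel 54 µm volumes at (2, 1, 1) µm voxels: channel A
(GFP, genetically encoded) spans the full depth and may clip at the
antibody-entry face; channel B (the antibody-stained marker) is confined to
the top `penetration_fraction` of the depth. Each B cell is planted to
overlap a random A cell with probability `overlap_fraction` (Bernoulli, so
counts carry binomial error). The study preset uses 271 A and 31 B cells
per stack over 13 stacks with overlap 0.92 and penetration 0.24; these
counts are taken from the published cell tallies and jointly reproduce,
with no further tuning, the unrestricted (~11%) and depth-restricted
(~44%) co-expression fractions of the full-depth channel.

## Trace processing

- **ΔF/F₀**: F₀ = 10th percentile of the baseline window (default: the
  control epoch). Non-positive F₀ raises `UnusableTraceError`.
- **Band-pass**: 4th-order Butterworth, 0.01–0.15 Hz, applied
  forward–backward (`sosfiltfilt`) with even-reflection padding of one
  low-cut period. Even reflection matters: odd reflection extrapolates the
  edge slope and inflates edge variance ~3×, a deterministic envelope
  shared by all cells that biases pairwise correlations upward. The DC
  offset (common to all cells because F₀ is a low percentile) is removed
  before filtering for the same reason.
- **Noise scale**: 1.4826·MAD of the *second* differences /√6 of the raw
  ΔF/F₀. First differences are inflated ~1.5× by transient slopes at
  neuronal rates; differencing twice suppresses the smooth signal while
  amplifying white noise by a known factor. After filtering the scale is
  shrunk by √(band width / Nyquist), the band's share of the noise power.
- **Peak detection**: local maxima with prominence ≥ 6× the filtered-trace
  noise scale (with a 5%-of-max floor that rejects zero-phase filter
  ringing on noise-free traces), separated by ≥ 3.5 s (half the high-cut
  period; longer separations clip genuine short gamma intervals).
- **Statistics**: frequency = 60·(peaks in epoch)/(epoch s); interval
  CV = 100·sd/mean of successive intervals, NaN below 3 peaks; active =
  ≥ 2 peaks in the control epoch, so a single evoked transient never
  reclassifies a dormant cell. Epochs are half-open [start, end).

### Calibration

The detector has two jointly binding requirements: (i) band-limited noise
alone must essentially never produce a countable peak (otherwise dormant
cells misclassify as active), and (ii) the dip between transients ~5 s
apart must stay resolvable (otherwise counting at neuronal rates biases
low). These fix the working point: at 6× the filtered noise scale the
false-peak rate is ≈ 0.1 per 5 min (0/300 dormant cells misclassified)
while planted rates recover within 10% across 0.8–7 cycles/min; at 5× or
below, 5–50% of dormant cells misclassify. The preset SNR (amplitude 0.45,
noise 0.015) is the regime in which both requirements can hold at once —
with substantially noisier traces the noise-prominence tail and the
true-dip distribution overlap and no threshold satisfies both.

**Known limit**: above ~7 cycles/min (period approaching the 6.7 s
high-cut period) counting saturates — at a planted 8 cycles/min the
detected rate is ≈ −13% — because a CV-33% interval distribution puts mass
below the post-filter resolution floor (~5 s). This is a property of the
0.01–0.15 Hz band, not of the detector. Its sharpest consequence: a
doubled neuronal rate (6.4 → 12.8 cycles/min, 0.21 Hz) is *outside the
band entirely*; the detected rate at a planted 12.8 cycles/min is
≈ 5.9 cycles/min. The agonist-induced neuronal doubling in the pFRG/RTN is
therefore verifiable on the generator's ground truth but not recoverable by
band-passed peak counting, and the test suite carries one deliberately
failing test documenting exactly this. For the same reason the hypercapnic
fold change is reported for the astrocytic population (1.1 → 2.2
cycles/min stays in-band), which is also the physiologically meaningful
readout — astrocytes are the CO₂ sensors.

## Network inference

Correlations are zero-lag Pearson r between band-passed ΔF/F₀ traces of
active cells over an epoch (a max-lag variant over ±4 s is available, since
"precisely timed" astrocyte–neuron pairing may tolerate small lags).
Constant traces are excluded with a warning. The cut-off comes from
surrogate pairs: one trace of a random pair circularly shifted by ≥ 10 s,
correlation computed with the same estimator; default cut-off = the 99th
percentile of ≥ 100 such draws.

The *study pipeline* uses a stricter, family-wise variant — the maximum
over 5000 surrogate draws — and 20-minute recordings. With ~5–7×10³
simultaneous pairs, a 1% per-pair false-positive rate plants ~50–200
spurious edges, enough to fuse the planted assemblies into giant clusters
(measured mean neuronal cluster size 74 instead of 5.8). Independent
quasi-periodic cells decorrelate with recording length while planted
within-assembly correlations are stationary, so at 1200 s the family-wise
cut-off (~0.28) passes essentially all planted pairs and fewer than one
false edge per slice.

Partition: astrocytic subgraph (induced on GFAP+), neuronal subgraph
(GFAP−), mixed edges (one endpoint of each); the three sets partition the
edges exactly. A cluster is a connected component of ≥ 2 cells within a
label-restricted subgraph — a functional analogue of a morphological
definition from the literature; isolated active cells are excluded from
cluster metrics. `connections_per_cell` is the mean subgraph degree over
clustered nodes.

## IHC quantification

Per channel: background subtraction by per-plane Gaussian (σ = 25 px),
Otsu threshold on the corrected volume, 3-D connected components with
26-connectivity, minimum size 20 voxels (≈ a quarter of an 8 µm soma at
the configured voxel size, so face-clipped somata still count) as the
reproducible surrogate for manual artefact curation. Touching cells merge
into one ROI — a documented limitation; no watershed is attempted. A cell
is double-labeled when its mask shares ≥ 1 voxel with any ROI of the other
channel (a literal reading of overlapping ROIs; the threshold is
configurable). Penetration = deepest ROI centroid / stack depth, measured
from the antibody-entry face. The depth-restricted re-count keeps only
ROIs whose centroids lie within the depth range spanned by the restricting
channel.

## Statistics

The slice is the statistical unit everywhere: per-cell values are averaged
within slice before testing. Fold changes are means of per-slice
post/pre ratios with a paired t-test; "blunted" is operationalised as
ratio ≤ 1.2 with a non-significant paired test. A PGE2 response is a
transient when the level exceeds baseline by > 2 baseline SDs and some
post-peak sample returns to within 2 SDs. Group tests: Student's t
(paired or Welch) and full-factorial ANOVA via OLS; significance p < 0.05,
no multiplicity correction. The t-test's type-I error is verified at
≈ 5% on Gaussian nulls in the test suite.

## What the synthetic data does and does not establish

Passing tests show that the pipeline recovers planted rates, interval CVs,
active fractions, assembly structure, stimulus folds and colocalization
fractions under the stated conditions: gamma-renewal event trains, a fixed
transient kernel, additive white noise at clean-imaging SNR, and
assembly-structured correlations. Real recordings add features the
generator deliberately omits: baseline drift and photobleaching, movement,
neuropil contamination, amplitude adaptation within bursts, cell-to-cell
kernel variability, non-stationary rates, and optical crosstalk between
channels in the IHC volumes. Results on real data therefore depend on the
preprocessing handling those effects; the band-pass and robust noise
estimates help, but none of these artefacts is simulated here. Group-size
choices in the tests and the acceptance script (19 / 22 slices, 13 stacks,
5-min control epochs, 20-min network recordings) are the package's study
defaults, chosen to match the published group sizes.
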