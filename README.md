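# caslice — calcium-imaging slice analysis

`caslice` analyses two-population calcium-imaging recordings from
organotypic brainstem slice cultures, where astrocytes (GFAP+) and neurons
(GFAP−) of the respiratory centres — the parafacial respiratory group /
retrotrapezoid nucleus (pFRG/RTN) and the preBötzinger complex (preBötC) —
show rhythmic Ca²⁺ oscillations. It is written for experimenters who have
per-cell fluorescence traces (0.5 s sampling), cell positions and cell-type
labels, and want oscillation statistics, functional connectivity and
stimulation-response summaries, plus two-channel immunolabel quantification
for the accompanying histology.

Because raw recordings of this kind are rarely shareable, the package
includes a first-class synthetic-slice generator whose named presets
reproduce the published summary statistics of both respiratory centres, so
every stage of the pipeline can be validated against planted ground truth.

## What it computes

**Per-cell oscillation statistics** (`caslice.traces`). Traces are
normalised to ΔF/F₀ with F₀ the 10th percentile of the control epoch,
band-pass filtered 0.01–0.15 Hz (zero-phase Butterworth), and peaks are
detected as local maxima with prominence above a noise-calibrated
threshold. For a peak train t₁ < … < t_n in an epoch of length T:

- frequency  f = 60·n/T  (cycles/min),
- interval variability  CV = 100·sd(Δt)/mean(Δt)  (%), Δt the successive
  inter-peak intervals,
- a cell is *active* when it shows ≥ 2 peaks in the control epoch.

**Functional networks** (`caslice.network`). Edges connect active-cell
pairs whose filtered ΔF/F₀ traces have Pearson r ≥ a cut-off, taken either
as a fixed value or from circularly time-shifted surrogate pairs. The graph
partitions into the astrocytic subgraph, the neuronal subgraph and the
mixed (astrocyte–neuron) edge set; a *cluster* is a connected component of
≥ 2 cells within a label-restricted subgraph, summarised by mean cells per
cluster and mean connections per cell.

**Stimulus responses** (`caslice.stats`). Paired control→stimulus
frequency fold changes per slice (slice = statistical unit), for astrocyte
activation through the exogenous MrgA1 receptor (FLRF peptide), for
hypercapnia (CO₂ 4.6 → 6.6 kPa), and for perfusate PGE2 timecourses;
Student's t-tests and full-factorial ANOVA.

**IHC quantification** (`caslice.roi`). Background subtraction, Otsu
thresholding, 3-D connected components with a minimum-size filter,
cross-channel double-label counting by mask overlap, antibody-penetration
depth, and depth-restricted re-counts.

## Worked example

```python
from caslice.synthetic import generate_preset_slice
from caslice.traces import analyze_recording
from caslice.network import infer_network, partition, cluster_metrics, edge_fractions

rec = generate_preset_slice("preBotC", "control", seed=42, duration_s=1200.0)
table = analyze_recording(rec)
ctl = table[table.epoch == "control"]

astro = ctl[ctl.label == "astrocyte"]
neuron = ctl[ctl.label == "neuron"]
print(f"astrocytes: {len(astro)} cells, {100*astro.active.mean():.0f}% active, "
      f"{astro[astro.active].frequency_cpm.mean():.2f} cycles/min")
print(f"neurons:    {len(neuron)} cells, {100*neuron.active.mean():.0f}% active, "
      f"{neuron[neuron.active].frequency_cpm.mean():.2f} cycles/min")

idx = {cid: i for i, cid in enumerate(rec.cell_ids)}
active = [idx[c] for c in ctl[ctl.active].cell_id]
net = infer_network(rec, active, seed=42, n_shuffles=5000,
                    surrogate_percentile=100.0)
fr = edge_fractions(net)
astro_g, neuron_g, mixed = partition(net)
m = cluster_metrics(neuron_g)
print(f"network: {net.n_nodes} active cells, {net.n_edges} edges at r >= {net.cutoff:.2f}")
print(f"edge types: {100*fr['astro_astro']:.0f}% astro-astro, "
      f"{100*fr['neuron_neuron']:.0f}% neuron-neuron, {100*fr['mixed']:.0f}% mixed")
print(f"neuronal clusters: {m.n_clusters} clusters, "
      f"{m.cells_per_cluster:.1f} cells/cluster, "
      f"{m.connections_per_cell:.1f} connections/cell")
```

prints:

```
astrocytes: 183 cells, 14% active, 1.17 cycles/min
neurons:    117 cells, 82% active, 4.99 cycles/min
network: 121 active cells, 375 edges at r >= 0.37
edge types: 16% astro-astro, 60% neuron-neuron, 24% mixed
neuronal clusters: 16 clusters, 5.8 cells/cluster, 4.8 connections/cell
```

Reading: most astrocytes are dormant; the active minority oscillates an
order of magnitude slower (~1.2 cycles/min) than the neurons (~5
cycles/min). Thresholding pairwise correlations at the surrogate cut-off
(r ≥ 0.37 here) recovers the planted assembly structure: a predominantly
neuronal network (60% of correlating pairs) with a distinct astrocytic
subnetwork (16%) joined to it by astrocyte–neuron edges (24%), and
neuronal clusters of ≈ 5.8 cells with ≈ 4.8 connections each.

A command-line interface mirrors the library:

```sh
caslice simulate --region pFRG/RTN --seed 7 --out rec.csv
caslice traces --input rec.csv --out stats.csv
caslice network --input rec.csv --cutoff surrogate:99 --out net
caslice ihc --seed 7 --n-stacks 4 --outdir ihc/
caslice study --seed 7 --outdir study/
```

## Layout

| module | contents |
| --- | --- |
| `caslice.types` | domain dataclasses (recordings, specs, reports) |
| `caslice.synthetic` | slice/stack/timecourse generators + study presets |
| `caslice.traces` | ΔF/F₀, band-pass, peak detection, per-cell statistics |
| `caslice.network` | correlation, surrogate cut-off, partition, clusters |
| `caslice.roi` | IHC segmentation, colocalization, penetration depth |
| `caslice.stats` | summaries, fold changes, t-tests, ANOVA |
| `caslice.io` / `caslice.cli` | CSV/JSON/TIFF/GraphML I/O and the CLI |
| `caslice.plotting` | trace, network and boxplot figures |

Model details, parameter defaults and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
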