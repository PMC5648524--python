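"""Reading and writing the pipeline's file formats.

A slice recording is stored as a trace CSV (one row per sample, one column
per cell, header = cell IDs) plus a JSON sidecar holding region, sampling
interval, positions, GFAP labels, the protocol, and — for synthetic slices
— the planted ground truth.  Image stacks are multi-page TIFFs with one
file per channel; networks export to GraphML; PGE2 timecourses and all
tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .network import FunctionalNetwork
from .types import (
    FluorescenceTrace,
    GroundTruth,
    LabeledImageStack,
    Pge2Timecourse,
    SliceRecording,
    StimulusProtocol,
)


# ---------------------------------------------------------------------------
# slice recordings
# ---------------------------------------------------------------------------

def write_recording(recording: SliceRecording, csv_path: str | Path,
                    meta_path: Optional[str | Path] = None) -> None:
    """Write traces to CSV and metadata (+ ground truth) to a JSON sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    df = pd.DataFrame(recording.values_matrix().T, columns=recording.cell_ids)
    df.to_csv(csv_path, index=False, float_format="%.6g")

    meta: dict = {
        "region": recording.region,
        "slice_id": recording.slice_id,
        "sampling_interval_s": recording.sampling_interval_s,
        "positions_um": recording.positions.tolist(),
        "gfap_positive": recording.gfap_positive.astype(int).tolist(),
        "protocol": vars(recording.protocol).copy(),
    }
    if recording.ground_truth is not None:
        gt = recording.ground_truth
        meta["ground_truth"] = {
            "active": gt.active.astype(int).tolist(),
            "frequency_cpm": gt.frequency_cpm.tolist(),
            "assembly_id": gt.assembly_id.tolist(),
            "locked": gt.locked.astype(int).tolist(),
            "amplitude": gt.amplitude.tolist(),
            "peak_times_s": [p.tolist() for p in gt.peak_times_s],
        }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_recording(csv_path: str | Path,
                   meta_path: Optional[str | Path] = None) -> SliceRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    dt = float(meta["sampling_interval_s"])
    traces = [FluorescenceTrace(df[c].to_numpy(), dt, c) for c in df.columns]
    truth = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        truth = GroundTruth(
            active=np.asarray(g["active"], dtype=bool),
            frequency_cpm=np.asarray(g["frequency_cpm"]),
            assembly_id=np.asarray(g["assembly_id"]),
            locked=np.asarray(g["locked"], dtype=bool),
            amplitude=np.asarray(g["amplitude"]),
            peak_times_s=[np.asarray(p) for p in g["peak_times_s"]],
        )
    return SliceRecording(
        region=meta["region"],
        traces=traces,
        positions=np.asarray(meta["positions_um"]),
        gfap_positive=np.asarray(meta["gfap_positive"], dtype=bool),
        protocol=StimulusProtocol(**meta["protocol"]),
        sampling_interval_s=dt,
        ground_truth=truth,
        slice_id=meta.get("slice_id", ""),
    )


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_stack(stack: LabeledImageStack, base_path: str | Path) -> list[Path]:
    """Write each channel as <base>_<channel>.tif (pages = z planes)."""
    base = Path(base_path)
    paths = []
    for name, vol in stack.channels.items():
        p = base.parent / f"{base.stem}_{name}.tif"
        tifffile.imwrite(p, vol.astype(np.float32))
        paths.append(p)
    return paths


def read_stack_channel(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# networks, tables, timecourses
# ---------------------------------------------------------------------------

def write_network(network: FunctionalNetwork, graphml_path: str | Path,
                  edge_csv_path: Optional[str | Path] = None) -> None:
    """GraphML export plus an optional (cell_i, cell_j, r, edge_type) CSV."""
    from .network import edge_type as _etype

    g = network.graph.copy()
    for n, d in g.nodes(data=True):
        d["x_um"], d["y_um"] = d.pop("pos")
        d["gfap_positive"] = int(d["gfap_positive"])
    nx.write_graphml(g, graphml_path)
    if edge_csv_path is not None:
        rows = [{"cell_i": network.graph.nodes[u]["cell_id"],
                 "cell_j": network.graph.nodes[v]["cell_id"],
                 "r": d["r"],
                 "edge_type": _etype(network.graph, u, v)}
                for u, v, d in network.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["cell_i", "cell_j", "r", "edge_type"]) \
            .to_csv(edge_csv_path, index=False)


def write_pge2(tc: Pge2Timecourse, path: str | Path) -> None:
    pd.DataFrame({"time_min": tc.times_min,
                  "concentration": tc.concentration}).to_csv(path, index=False)


def read_pge2(path: str | Path, stimulus_onset_min: float) -> Pge2Timecourse:
    df = pd.read_csv(path)
    return Pge2Timecourse(times_min=df["time_min"].to_numpy(),
                          concentration=df["concentration"].to_numpy(),
                          stimulus_onset_min=stimulus_onset_min)
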