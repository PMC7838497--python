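"""File formats: HDF5 trace containers, CSV tables, TIFF movies, YAML/JSON.

Traces plus their ground truth travel in a single hierarchical HDF5
container; event tables, binned series and rasters are flat CSV; movies are
multi-page TIFF; configurations are YAML; reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .caimg import BinaryRaster, Movie, RawTraceSet
from .epsc import BinnedSeries, CurrentTrace, EventTrain
from .protocol import DrugProtocol, Epoch
from .synth import SimTruth

__all__ = [
    "protocol_to_dict",
    "protocol_from_dict",
    "save_epsc_h5",
    "load_epsc_h5",
    "save_calcium_h5",
    "load_calcium_h5",
    "load_trace_csv",
    "save_events_csv",
    "save_binned_csv",
    "save_raster_csv",
    "load_raster_csv",
    "save_traces_csv",
    "load_traces_csv",
    "save_movie_tiff",
    "load_movie_tiff",
    "load_config_yaml",
    "save_report_json",
    "load_report_json",
]


# ---------------------------------------------------------------------------
# protocol


def protocol_to_dict(protocol: DrugProtocol) -> dict:
    return {
        "epochs": [[e.label, e.start, e.end] for e in protocol.epochs],
        "drug_rate_ratio": protocol.drug_rate_ratio,
        "drug_amp_ratio": protocol.drug_amp_ratio,
        "onset_tau": protocol.onset_tau,
        "washout_persistence": protocol.washout_persistence,
    }


def protocol_from_dict(d: dict) -> DrugProtocol:
    epochs = [Epoch(str(l), float(s), float(e)) for l, s, e in d["epochs"]]
    return DrugProtocol(
        epochs=epochs,
        drug_rate_ratio=float(d.get("drug_rate_ratio", 2.72)),
        drug_amp_ratio=float(d.get("drug_amp_ratio", 2.40)),
        onset_tau=float(d.get("onset_tau", 60.0)),
        washout_persistence=float(d.get("washout_persistence", 1.0)),
    )


# ---------------------------------------------------------------------------
# HDF5 containers


def _write_protocol(g: h5py.Group, protocol: DrugProtocol | None) -> None:
    if protocol is None:
        return
    g.attrs["protocol_json"] = json.dumps(protocol_to_dict(protocol))


def _read_protocol(g: h5py.Group) -> DrugProtocol | None:
    if "protocol_json" not in g.attrs:
        return None
    return protocol_from_dict(json.loads(g.attrs["protocol_json"]))


def save_epsc_h5(path: str | Path, trace: CurrentTrace, truth: SimTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        g.create_dataset("samples", data=trace.samples, compression="gzip")
        g.attrs["sampling_rate"] = trace.sampling_rate
        g.attrs["holding_potential"] = trace.holding_potential
        g.attrs["cell_id"] = trace.cell_id
        _write_protocol(g, trace.protocol)
        if truth is not None:
            t = f.create_group("truth")
            t.create_dataset("event_times", data=truth.epsc_event_times)
            t.create_dataset("amplitudes", data=truth.epsc_amplitudes)
            t.create_dataset("in_burst", data=truth.epsc_in_burst.astype(np.uint8))
            t.attrs["params_json"] = json.dumps(truth.params)


def load_epsc_h5(path: str | Path) -> tuple[CurrentTrace, SimTruth | None]:
    with h5py.File(path, "r") as f:
        g = f["trace"]
        trace = CurrentTrace(
            g["samples"][...],
            float(g.attrs["sampling_rate"]),
            float(g.attrs["holding_potential"]),
            _read_protocol(g),
            str(g.attrs["cell_id"]),
        )
        truth = None
        if "truth" in f:
            t = f["truth"]
            truth = SimTruth(
                epsc_event_times=t["event_times"][...],
                epsc_amplitudes=t["amplitudes"][...],
                epsc_in_burst=t["in_burst"][...].astype(bool),
                params=json.loads(t.attrs["params_json"]),
                protocol=trace.protocol,
            )
    return trace, truth


def save_calcium_h5(
    path: str | Path,
    traces: RawTraceSet,
    truth: SimTruth | None = None,
    protocol: DrugProtocol | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        g.create_dataset("f", data=traces.traces, compression="gzip")
        g.attrs["frame_rate"] = traces.frame_rate
        g.attrs["cell_ids"] = json.dumps(traces.cell_ids)
        _write_protocol(g, protocol)
        if truth is not None:
            t = f.create_group("truth")
            for i, frames in enumerate(truth.cell_event_frames):
                t.create_dataset(f"cell_event_frames/{i}", data=frames)
            t.create_dataset("ensemble_frames", data=truth.ensemble_frames)
            t.attrs["params_json"] = json.dumps(truth.params)


def load_calcium_h5(
    path: str | Path,
) -> tuple[RawTraceSet, SimTruth | None, DrugProtocol | None]:
    with h5py.File(path, "r") as f:
        g = f["traces"]
        traces = RawTraceSet(
            g["f"][...], float(g.attrs["frame_rate"]), json.loads(g.attrs["cell_ids"])
        )
        protocol = _read_protocol(g)
        truth = None
        if "truth" in f:
            t = f["truth"]
            n = len(t["cell_event_frames"])
            truth = SimTruth(
                cell_event_frames=[
                    t[f"cell_event_frames/{i}"][...].astype(int) for i in range(n)
                ],
                ensemble_frames=t["ensemble_frames"][...].astype(int),
                params=json.loads(t.attrs["params_json"]),
                protocol=protocol,
            )
    return traces, truth, protocol


# ---------------------------------------------------------------------------
# CSV tables


def load_trace_csv(
    path: str | Path,
    sampling_rate: float | None = None,
    protocol: DrugProtocol | None = None,
    cell_id: str | None = None,
) -> CurrentTrace:
    """Columnar time series with ``time_s`` and ``current_pA`` columns.

    A bare single-column file is accepted if ``sampling_rate`` is given.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "current_pa" in cols:
        current = df[cols["current_pa"]].to_numpy(float)
    else:
        current = df[df.columns[-1]].to_numpy(float)
    if "time_s" in cols:
        t = df[cols["time_s"]].to_numpy(float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer the sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
    elif sampling_rate is not None:
        fs = sampling_rate
    else:
        raise ValueError("no time_s column and no sampling_rate given")
    return CurrentTrace(current, fs, protocol=protocol, cell_id=cell_id or Path(path).stem)


def save_events_csv(
    path: str | Path,
    train: EventTrain,
    protocol: DrugProtocol | None = None,
    burst_ids: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame({"time_s": train.times, "amplitude_pA": train.amplitudes})
    if protocol is not None:
        df["epoch"] = [protocol.label_at(t) or "" for t in train.times]
    if burst_ids is not None:
        df["burst_id"] = burst_ids
    df.to_csv(path, index=False)


def save_binned_csv(path: str | Path, series: BinnedSeries) -> None:
    pd.DataFrame(
        {
            "bin_start_s": series.bin_edges[:-1],
            "bin_end_s": series.bin_edges[1:],
            "value": series.values,
        }
    ).to_csv(path, index=False)


def save_raster_csv(path: str | Path, raster: BinaryRaster) -> None:
    pd.DataFrame(raster.matrix).to_csv(path, index=False, header=False)


def load_raster_csv(path: str | Path, frame_rate: float) -> BinaryRaster:
    mat = pd.read_csv(path, header=None).to_numpy()
    return BinaryRaster(mat, frame_rate)


def save_traces_csv(path: str | Path, traces: RawTraceSet) -> None:
    df = pd.DataFrame(traces.traces.T, columns=traces.cell_ids)
    df.insert(0, "frame", np.arange(traces.n_frames))
    df.to_csv(path, index=False)


def load_traces_csv(path: str | Path, frame_rate: float) -> RawTraceSet:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "frame"]
    return RawTraceSet(df[cols].to_numpy(float).T, frame_rate, cols)


# ---------------------------------------------------------------------------
# TIFF movies


def save_movie_tiff(path: str | Path, movie: Movie) -> None:
    tifffile.imwrite(
        path,
        movie.frames.astype(np.float32),
        metadata={"frame_rate": movie.frame_rate, "pixel_size_um": movie.pixel_size},
    )


def load_movie_tiff(
    path: str | Path, frame_rate: float | None = None, pixel_size: float | None = None
) -> Movie:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    fr = frame_rate if frame_rate is not None else float(meta.get("frame_rate", 4.0))
    px = pixel_size if pixel_size is not None else float(meta.get("pixel_size_um", 1.0))
    return Movie(np.asarray(frames, dtype=float), fr, px)


# ---------------------------------------------------------------------------
# YAML / JSON


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_report_json(path: str | Path, report: Any) -> None:
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
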