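"""Experiment orchestration: configuration, pipelines, and reports.

A single configuration drives both arms of an experiment:

* the sEPSC arm — noise estimation → event detection → 10-s-bin histograms
  → baseline normalization → 5-min maximal-effect window → bursts →
  per-cell responsiveness, with the group-level effect computed the way
  spontaneous-release pharmacology reports it: per-cell normalized
  histograms are averaged across cells first, and the maximal-effect window
  is read off the group average;
* the calcium arm — (movie → ROIs →) ΔF/F → transient onsets → binary
  raster → coactivity + Monte Carlo surrogate threshold → per-cell activity
  per condition → KS/Friedman comparisons.

Reports are plain JSON-able dictionaries wrapped with provenance (package
version, configuration hash, seeds), so every number is reproducible from
the report alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__, caimg, epsc, io, synth
from .protocol import DrugProtocol

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_epsc_pipeline",
    "run_calcium_pipeline",
    "group_effect_estimate",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ExperimentConfig:
    """Inputs and analysis parameters for one experiment.

    Exactly one source per arm: simulation parameters (``epsc_sim`` /
    ``calcium_sim``) or input paths. Defaults mirror the acquisition and
    analysis constants of the recordings this pipeline emulates: 10-s bins,
    a 5-min maximal-effect window, detection threshold 3×SD for currents
    and 2.5×SD for ΔF/F transients, 1,000 surrogates, alpha 0.05.
    """

    protocol: DrugProtocol
    seed: int = 0
    # sEPSC arm
    epsc_sim: synth.EpscSimParams | None = None
    n_epsc_cells: int = 1
    epsc_paths: list[str] = field(default_factory=list)
    bin_width: float = 10.0  # s
    effect_window: float = 300.0  # s
    k_threshold: float = 3.0
    refractory_ms: float = 2.0
    noise_window: tuple[float, float] | None = None
    response_window: float = 600.0  # s
    # calcium arm
    calcium_sim: synth.CalciumSimParams | None = None
    calcium_traces_path: str | None = None
    movie_path: str | None = None
    render: bool = False  # simulate a movie and analyze it end-to-end
    k_amp: float = 2.5
    k_deriv: float = 2.5
    f0_percentile: float = 10.0
    n_surrogates: int = 1000
    alpha: float = 0.05
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        if "protocol" not in d:
            raise ValueError("configuration must define a protocol")
        kw: dict[str, Any] = {"protocol": io.protocol_from_dict(d["protocol"])}
        for key in (
            "seed", "n_epsc_cells", "epsc_paths", "bin_width", "effect_window",
            "k_threshold", "refractory_ms", "response_window", "k_amp", "k_deriv",
            "f0_percentile", "n_surrogates", "alpha", "out_dir",
            "calcium_traces_path", "movie_path", "render",
        ):
            if key in d:
                kw[key] = d[key]
        if "noise_window" in d and d["noise_window"] is not None:
            kw["noise_window"] = tuple(d["noise_window"])
        if "epsc_sim" in d and d["epsc_sim"] is not None:
            kw["epsc_sim"] = synth.EpscSimParams(**d["epsc_sim"])
        if "calcium_sim" in d and d["calcium_sim"] is not None:
            kw["calcium_sim"] = synth.CalciumSimParams(**d["calcium_sim"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(io.load_config_yaml(path))

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "protocol": io.protocol_to_dict(self.protocol),
            "seed": self.seed,
            "n_epsc_cells": self.n_epsc_cells,
            "epsc_paths": list(self.epsc_paths),
            "bin_width": self.bin_width,
            "effect_window": self.effect_window,
            "k_threshold": self.k_threshold,
            "refractory_ms": self.refractory_ms,
            "noise_window": list(self.noise_window) if self.noise_window else None,
            "response_window": self.response_window,
            "calcium_traces_path": self.calcium_traces_path,
            "movie_path": self.movie_path,
            "render": self.render,
            "k_amp": self.k_amp,
            "k_deriv": self.k_deriv,
            "f0_percentile": self.f0_percentile,
            "n_surrogates": self.n_surrogates,
            "alpha": self.alpha,
            "out_dir": self.out_dir,
        }
        if self.epsc_sim is not None:
            d["epsc_sim"] = _jsonable(synth.asdict(self.epsc_sim))
        if self.calcium_sim is not None:
            d["calcium_sim"] = _jsonable(synth.asdict(self.calcium_sim))
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# report


@dataclass
class ExperimentReport:
    """A JSON-able experiment record: results plus provenance."""

    kind: str
    config: dict
    results: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "config": self.config,
            "results": self.results,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentReport":
        d = json.loads(text)
        return cls(d["kind"], d["config"], d["results"], d["provenance"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _provenance(config: ExperimentConfig) -> dict:
    return {
        "package": "synaptoscope",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
    }


# ---------------------------------------------------------------------------
# group-level effect


def group_effect_estimate(
    normalized: Sequence[epsc.BinnedSeries],
    protocol: DrugProtocol,
    width: float = 300.0,
) -> dict:
    """Average normalized per-cell histograms, then take the 5-min maximal window.

    Returns the group percent-of-baseline value in the window and the
    percent change over baseline (value − 100).
    """
    if not normalized:
        raise ValueError("no series to average")
    edges = normalized[0].bin_edges
    vals = np.nanmean(np.vstack([s.values for s in normalized]), axis=0)
    group = epsc.BinnedSeries(edges, vals, kind=normalized[0].kind, normalized=True)
    window = epsc.select_effect_window(group, protocol, width)
    level = float(np.nanmean(group.bins_in(*window)))
    return {
        "window": list(window),
        "percent_of_baseline": level,
        "percent_change": level - 100.0,
        "group_series": _jsonable(vals),
        "bin_edges": _jsonable(edges),
    }


# ---------------------------------------------------------------------------
# sEPSC pipeline


def _epsc_traces(config: ExperimentConfig):
    if config.epsc_sim is not None:
        for i in range(config.n_epsc_cells):
            params = replace(config.epsc_sim, seed=config.epsc_sim.seed + i)
            trace, truth = synth.simulate_epsc_trace(
                params, config.protocol, cell_id=f"simcell{i}"
            )
            yield trace, truth
    elif config.epsc_paths:
        for p in config.epsc_paths:
            if str(p).endswith((".h5", ".hdf5")):
                trace, truth = io.load_epsc_h5(p)
                trace.protocol = trace.protocol or config.protocol
            else:
                trace = io.load_trace_csv(p, protocol=config.protocol)
                truth = None
            yield trace, truth
    else:
        raise ValueError("no sEPSC inputs: set epsc_sim or epsc_paths")


def run_epsc_pipeline(config: ExperimentConfig) -> ExperimentReport:
    """Full sEPSC analysis for every input cell plus the group effect."""
    if config.protocol is None:
        raise ValueError("pipeline requires a protocol")
    protocol = config.protocol
    ctrl = protocol.control
    has_drug = bool(protocol.drug_epochs)
    cells = []
    norm_freq, norm_amp = [], []
    for trace, _truth in _epsc_traces(config):
        nw = config.noise_window or (ctrl.start, min(ctrl.start + 60.0, ctrl.end))
        noise = epsc.estimate_noise(trace, nw)
        train = epsc.detect_events(
            trace, noise, config.k_threshold, config.refractory_ms
        )
        freq = epsc.bin_frequency(train, config.bin_width, trace.duration)
        amp = epsc.bin_amplitude(train, config.bin_width, trace.duration)
        baseline_freq = float(np.mean(freq.bins_in(ctrl.start, ctrl.end)))
        cell: dict[str, Any] = {
            "cell_id": trace.cell_id,
            "noise_sd_pA": noise.sd,
            "n_events": len(train),
            "baseline_freq_hz": baseline_freq,
        }
        base_amp = amp.bins_in(ctrl.start, ctrl.end)
        base_amp = base_amp[np.isfinite(base_amp)]
        cell["baseline_amp_pA"] = float(np.mean(base_amp)) if base_amp.size else None

        if has_drug:
            nfreq = epsc.normalize_to_baseline(freq, protocol)
            norm_freq.append(nfreq)
            try:
                namp = epsc.normalize_to_baseline(amp, protocol)
                norm_amp.append(namp)
            except ValueError:
                namp = None
            window = epsc.select_effect_window(nfreq, protocol, config.effect_window)
            cell["effect_window"] = list(window)
            cell["pct_change_freq"] = float(np.nanmean(nfreq.bins_in(*window))) - 100.0
            if namp is not None:
                cell["pct_change_amp"] = float(np.nanmean(namp.bins_in(*window))) - 100.0
            responsive, res = epsc.responsive_cell(
                freq, protocol, config.alpha, config.response_window
            )
            cell["responsive"] = responsive
            cell["responsive_test"] = res.to_dict()
            if baseline_freq > 0:
                bursts = epsc.detect_bursts(train, baseline_freq)
                cell["bursts"] = [
                    {
                        "start_s": b.start,
                        "end_s": b.end,
                        "n_events": b.n_events,
                        "within_freq_hz": b.within_freq,
                    }
                    for b in bursts
                ]
                cell["n_bursts"] = len(bursts)
        cells.append(cell)

    results: dict[str, Any] = {"cells": cells, "n_cells": len(cells)}
    if has_drug and norm_freq:
        results["group_frequency"] = group_effect_estimate(
            norm_freq, protocol, config.effect_window
        )
        if norm_amp:
            results["group_amplitude"] = group_effect_estimate(
                norm_amp, protocol, config.effect_window
            )
        results["n_responsive"] = int(sum(c.get("responsive", False) for c in cells))
    report = ExperimentReport(
        "epsc", _jsonable(config.to_dict()), _jsonable(results), _provenance(config)
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_report_json(out / "epsc_report.json", report)
    return report


# ---------------------------------------------------------------------------
# calcium pipeline


def _calcium_traces(config: ExperimentConfig) -> tuple[caimg.RawTraceSet, Any]:
    if config.calcium_sim is not None:
        traces, truth = synth.simulate_calcium_traces(config.calcium_sim, config.protocol)
        if config.render:
            movie, _cells = synth.render_movie(traces, config.calcium_sim)
            rois = caimg.extract_rois(movie)
            return caimg.roi_traces(movie, rois), truth
        return traces, truth
    if config.movie_path:
        movie = io.load_movie_tiff(config.movie_path)
        rois = caimg.extract_rois(movie)
        return caimg.roi_traces(movie, rois), None
    if config.calcium_traces_path:
        p = config.calcium_traces_path
        if str(p).endswith((".h5", ".hdf5")):
            traces, truth, _proto = io.load_calcium_h5(p)
            return traces, truth
        fr = 4.0
        return io.load_traces_csv(p, fr), None
    raise ValueError("no calcium inputs: set calcium_sim, movie_path or calcium_traces_path")


def run_calcium_pipeline(config: ExperimentConfig) -> ExperimentReport:
    """Full calcium-imaging population analysis."""
    if config.protocol is None:
        raise ValueError("pipeline requires a protocol")
    raw, _truth = _calcium_traces(config)
    results: dict[str, Any] = {"n_cells": raw.n_cells, "n_frames": raw.n_frames}
    if raw.n_cells == 0:
        results.update({"raster": [], "coactivity": [], "significant_frames": []})
        return ExperimentReport(
            "calcium", _jsonable(config.to_dict()), results, _provenance(config)
        )
    dff = caimg.compute_dff(raw, f0_percentile=config.f0_percentile)
    transients = caimg.detect_transients(dff, config.k_amp, config.k_deriv)
    labels = config.protocol.condition_of_frame(dff.n_frames, dff.frame_rate)
    raster = caimg.binarize(transients, condition_of_frame=labels)
    co = caimg.monte_carlo_threshold(
        raster, config.n_surrogates, config.alpha, seed=config.seed
    )
    results.update(
        {
            "n_cells_analyzed": dff.n_cells,
            "excluded_cells": dff.excluded,
            "raster": _jsonable(raster.matrix),
            "coactivity": _jsonable(co.coactivity),
            "coactivity_threshold": co.threshold,
            "n_surrogates": co.n_surrogates,
            "significant_frames": _jsonable(co.significant_frames),
            "noise_sd": _jsonable(transients.noise_sd),
            "amp_threshold": _jsonable(transients.amp_threshold),
        }
    )
    conditions = {l for l in labels if l is not None}
    if all(l is not None for l in labels):
        summary = caimg.cell_activity(raster)
        results["activity"] = {
            "conditions": summary.conditions,
            "counts": _jsonable(summary.counts),
            "fractions": _jsonable(summary.fractions),
            "frames_per_condition": _jsonable(summary.frames_per_condition),
        }
        if len(summary.conditions) >= 3 and dff.n_cells >= 5:
            comp = caimg.compare_activity(summary)
            results["comparisons"] = {
                "ks": {k: v.to_dict() for k, v in comp["ks"].items()},
                "friedman": comp["friedman"].to_dict(),
                "measure": comp["measure"],
            }
    report = ExperimentReport(
        "calcium", _jsonable(config.to_dict()), _jsonable(results), _provenance(config)
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_report_json(out / "calcium_report.json", report)
    return report
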