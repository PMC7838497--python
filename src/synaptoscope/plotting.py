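"""Report figures: time-frequency histograms, ECDFs, raster + coactivity.

Rendering is best-effort — an empty or partial report produces empty axes
rather than an error — and deterministic: with the fixed style below, the
same report yields byte-identical SVG output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .epsc import cumulative_fraction

__all__ = ["plot_report"]

_STYLE = {"svg.hashsalt": "synaptoscope", "figure.dpi": 100}
_SAVEKW = {"metadata": {"Date": None, "Creator": "synaptoscope"}}


def _drug_band(ax, config: dict) -> None:
    for label, start, end in config.get("protocol", {}).get("epochs", []):
        if label == "drug":
            ax.axvspan(start, end, color="0.85", zorder=0)


def _plot_epsc(report_dict: dict, out: Path) -> list[Path]:
    paths = []
    results = report_dict.get("results", {})
    fig, ax = plt.subplots(figsize=(7, 3.2))
    group = results.get("group_frequency")
    if group:
        edges = np.asarray(group["bin_edges"])
        vals = np.asarray(group["group_series"])
        centers = 0.5 * (edges[:-1] + edges[1:])
        _drug_band(ax, report_dict.get("config", {}))
        ax.bar(centers, vals, width=edges[1] - edges[0], color="k")
        w0, w1 = group["window"]
        ax.axvspan(w0, w1, color="tab:red", alpha=0.15)
        ga = results.get("group_amplitude")
        if ga:
            ax.plot(centers, np.asarray(ga["group_series"]), ".", color="tab:green", ms=3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (% of baseline)")
    p = out / "time_frequency.svg"
    fig.savefig(p, **_SAVEKW)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    freqs = [c["baseline_freq_hz"] for c in results.get("cells", []) if "baseline_freq_hz" in c]
    if freqs:
        v, f = cumulative_fraction(freqs)
        ax.step(v, f, where="post", color="k")
    ax.set_xlabel("baseline frequency (Hz)")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.05)
    p = out / "cumulative_fraction.svg"
    fig.savefig(p, **_SAVEKW)
    plt.close(fig)
    paths.append(p)
    return paths


def _plot_calcium(report_dict: dict, out: Path) -> list[Path]:
    results = report_dict.get("results", {})
    raster = np.asarray(results.get("raster", []))
    co = np.asarray(results.get("coactivity", []))
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(7, 4), sharex=True, height_ratios=[3, 1]
    )
    if raster.size:
        cells, frames = np.nonzero(raster)
        ax0.plot(frames, cells, "|", color="k", ms=3)
        ax0.set_ylim(-0.5, raster.shape[0] - 0.5)
        ax0.set_xlim(-0.5, raster.shape[1] - 0.5)
    ax0.set_ylabel("cell")
    if co.size:
        ax1.bar(np.arange(co.size), co, width=1.0, color="k")
        thr = results.get("coactivity_threshold")
        if thr is not None:
            ax1.axhline(thr, color="tab:red", lw=0.8)
    ax1.set_xlabel("frame")
    ax1.set_ylabel("coactive cells")
    p = out / "raster_coactivity.svg"
    fig.savefig(p, **_SAVEKW)
    plt.close(fig)
    return [p]


def plot_report(report, out_dir: str | Path) -> list[Path]:
    """Render a report's figures into ``out_dir``; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    with plt.rc_context(_STYLE):
        if d.get("kind") == "calcium":
            return _plot_calcium(d, out)
        return _plot_epsc(d, out)
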