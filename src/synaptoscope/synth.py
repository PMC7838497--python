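"""Synthetic electrophysiology and calcium-imaging recordings with ground truth.

The generators emulate the statistical structure the downstream analysis
assumes, so every detection and inference stage can be validated against an
exported truth record (:class:`SimTruth`):

* voltage-clamp holding-current traces at 5 kHz with Poisson inward sEPSCs
  (biexponential kernel, lognormal amplitudes), drug-epoch rate/amplitude
  modulation with exponential onset and washout persistence, and optional
  bursts — short 50–150 ms clusters of events modelling synchronized
  multivesicular release;
* per-cell fluorescence traces at 4 frames/s with Poisson background
  transients, planted synchronous ensemble events, and Gaussian noise;
* rendered multi-page-TIFF-compatible movies of disk-shaped somata, so ROI
  extraction can be tested end to end.

All generation is reproducible: identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np

from .caimg import Movie, RawTraceSet
from .epsc import CurrentTrace
from .protocol import DrugProtocol

__all__ = [
    "EpscSimParams",
    "CalciumSimParams",
    "SimTruth",
    "PlacedCell",
    "simulate_epsc_trace",
    "simulate_calcium_traces",
    "render_movie",
]


# ---------------------------------------------------------------------------
# parameters and truth


@dataclass
class EpscSimParams:
    """Generator settings for a spontaneous-EPSC voltage-clamp recording.

    Defaults describe a typical AMPA-receptor-mediated sEPSC recording at
    −70 mV: 5 kHz sampling, a 3.5 Hz baseline event rate, ~20 pA median
    amplitude with right-skewed (lognormal) spread, 0.5/3 ms biexponential
    kinetics, and 2 pA baseline noise.
    """

    sampling_rate: float = 5000.0  # Hz
    duration: float | None = None  # s; defaults to the protocol span
    base_rate: float = 3.5  # Hz
    amp_median: float = 20.0  # pA
    amp_sigma_log: float = 0.4
    kernel_rise_tau: float = 0.5  # ms
    kernel_decay_tau: float = 3.0  # ms
    noise_sd: float = 2.0  # pA
    burst_rate: float = 0.0  # Hz, burst initiations during drug/wash
    burst_size_range: tuple[int, int] = (3, 6)
    intra_burst_interval: tuple[float, float] = (15.0, 25.0)  # ms
    refractory: float = 2.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if min(self.base_rate, self.burst_rate) < 0:
            raise ValueError("rates must be >= 0")
        if min(self.kernel_rise_tau, self.kernel_decay_tau) <= 0:
            raise ValueError("kernel taus must be > 0")
        if self.burst_size_range[0] < 3:
            raise ValueError("bursts need at least 3 events")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CalciumSimParams:
    """Generator settings for a bulk-loaded calcium-imaging recording.

    Defaults emulate a 280 × 260 μm field imaged at 4 frames/s, two dozen
    somata of ~12–20 μm diameter, sparse background transients (~0.03 Hz per
    cell), occasional planted ensemble (synchrony) events in which each cell
    participates with probability 0.6, 0.3 ΔF/F transient amplitude with a
    1.5 s decay, and 0.03 ΔF/F frame noise.
    """

    n_cells: int = 24
    frame_rate: float = 4.0  # frames/s
    n_frames: int | None = None  # derived from the protocol when None
    field_size: tuple[float, float] = (280.0, 260.0)  # μm (width, height)
    pixel_size: float = 1.0  # μm/px
    cell_diameter_range: tuple[float, float] = (12.0, 20.0)  # μm
    bg_event_rate: float = 0.03  # Hz per cell
    ensemble_rate: float = 0.01  # Hz
    participation_p: float = 0.6
    transient_amp: float = 0.3  # ΔF/F
    decay_tau: float = 1.5  # s
    noise_sd: float = 0.03  # ΔF/F
    condition_rate_ratios: dict = field(
        default_factory=lambda: {"control": 1.0, "drug": 2.0, "wash": 2.0}
    )
    bg_intensity: float = 100.0  # a.u., movie background
    cell_intensity: float = 300.0  # a.u., resting somatic fluorescence
    pixel_noise_sd: float = 2.0  # a.u., movie pixel noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.participation_p <= 1.0):
            raise ValueError("participation_p must lie in [0, 1]")
        lo, hi = self.cell_diameter_range
        if not (4.0 <= lo <= hi <= 30.0):
            raise ValueError("cell_diameter_range must lie within [4, 30] μm")
        if min(self.bg_event_rate, self.ensemble_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    For EPSC simulations: every inserted event's onset time, amplitude and
    burst membership. For calcium simulations: each cell's event frames and
    the planted ensemble frames. The generating parameters are echoed.
    """

    epsc_event_times: np.ndarray | None = None  # s, kernel onsets
    epsc_amplitudes: np.ndarray | None = None  # pA
    epsc_in_burst: np.ndarray | None = None  # bool per event
    cell_event_frames: list[np.ndarray] | None = None
    ensemble_frames: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    protocol: DrugProtocol | None = None

    def epoch_event_count(self, start: float, end: float) -> int:
        t = self.epsc_event_times
        return int(np.sum((t >= start) & (t < end)))


@dataclass(frozen=True)
class PlacedCell:
    center: tuple[float, float]  # (row, col) px
    diameter: float  # μm
    index: int


# ---------------------------------------------------------------------------
# sEPSC trace simulation


def _thinned_poisson(
    rng: np.random.Generator,
    rate_of_t,
    max_rate: float,
    t0: float,
    t1: float,
) -> np.ndarray:
    """Inhomogeneous Poisson times on [t0, t1) by thinning."""
    if max_rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(max_rate * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    if cand.size == 0:
        return cand
    keep = rng.uniform(size=cand.size) < rate_of_t(cand) / max_rate
    return cand[keep]


def _epsc_kernel(params: EpscSimParams) -> np.ndarray:
    """Unit-peak biexponential kernel sampled at the trace rate."""
    fs = params.sampling_rate
    tau_r = params.kernel_rise_tau * 1e-3
    tau_d = params.kernel_decay_tau * 1e-3
    length = int(np.ceil(7 * tau_d * fs)) + 1
    t = np.arange(length) / fs
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise tau >= decay tau?)")
    return k / peak


def simulate_epsc_trace(
    params: EpscSimParams, protocol: DrugProtocol, cell_id: str = "sim"
) -> tuple[CurrentTrace, SimTruth]:
    """Simulate a voltage-clamp holding-current trace with known events.

    Background events form an inhomogeneous Poisson process whose rate is
    ``base_rate`` × the protocol's drug-effect factor (exponential onset,
    washout persistence); amplitudes are lognormal scaled by the amplitude
    factor. Burst initiations occur at ``burst_rate`` during drug and wash
    epochs (synchronized release is a drug phenomenon here); each burst
    inserts ``burst_size`` events at the intra-burst spacing. Events closer
    than the refractory interval are merged (first one kept). The trace is
    the sum of negative-going unit-peak biexponential kernels scaled by the
    event amplitudes, plus white Gaussian noise.
    """
    duration = params.duration if params.duration is not None else protocol.end
    if duration < protocol.end - 1e-9:
        raise ValueError(
            f"duration {duration} s does not cover the protocol ({protocol.end} s)"
        )
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate

    # background events
    max_rate = params.base_rate * max(1.0, protocol.drug_rate_ratio)
    bg_times = _thinned_poisson(
        rng, lambda t: params.base_rate * protocol.rate_factor(t), max_rate, 0.0, duration
    )

    # burst events during drug and wash epochs
    burst_times = []
    in_burst_flags = []
    if params.burst_rate > 0:
        for e in protocol.epochs:
            if e.label == "control":
                continue
            n_bursts = rng.poisson(params.burst_rate * e.duration)
            starts = np.sort(rng.uniform(e.start, e.end, size=n_bursts))
            lo_n, hi_n = params.burst_size_range
            lo_i, hi_i = (v * 1e-3 for v in params.intra_burst_interval)
            for s in starts:
                size = int(rng.integers(lo_n, hi_n + 1))
                gaps = rng.uniform(lo_i, hi_i, size=size - 1)
                times = s + np.concatenate([[0.0], np.cumsum(gaps)])
                times = times[times < duration]
                burst_times.append(times)
                in_burst_flags.append(np.ones(times.size, dtype=bool))
    if burst_times:
        burst_times = np.concatenate(burst_times)
        in_burst = np.concatenate(in_burst_flags)
    else:
        burst_times = np.empty(0)
        in_burst = np.empty(0, dtype=bool)

    times = np.concatenate([bg_times, burst_times])
    flags = np.concatenate([np.zeros(bg_times.size, dtype=bool), in_burst])
    order = np.argsort(times, kind="stable")
    times, flags = times[order], flags[order]

    # refractory: drop events too close to the previously kept one
    if times.size:
        keep = np.ones(times.size, dtype=bool)
        last = -np.inf
        refr = params.refractory * 1e-3
        for i, t in enumerate(times):
            if t - last < refr:
                keep[i] = False
            else:
                last = t
        times, flags = times[keep], flags[keep]

    amps = (
        np.exp(rng.normal(np.log(params.amp_median), params.amp_sigma_log, times.size))
        * protocol.amp_factor(times)
    )

    n = int(round(duration * fs))
    trace = np.zeros(n)
    if times.size:
        kernel = _epsc_kernel(params)
        idx = np.round(times * fs).astype(int)
        for i0, a in zip(idx, amps):
            if i0 >= n:
                continue
            seg = min(kernel.size, n - i0)
            trace[i0 : i0 + seg] -= a * kernel[:seg]
    if params.noise_sd > 0:
        trace += rng.normal(0.0, params.noise_sd, n)

    truth = SimTruth(
        epsc_event_times=times,
        epsc_amplitudes=amps,
        epsc_in_burst=flags,
        params=asdict(params),
        protocol=protocol,
    )
    return CurrentTrace(trace, fs, -70.0, protocol, cell_id), truth


# ---------------------------------------------------------------------------
# calcium traces


def simulate_calcium_traces(
    params: CalciumSimParams, protocol: DrugProtocol
) -> tuple[RawTraceSet, SimTruth]:
    """Simulate per-cell fluorescence traces with known event frames.

    Each cell's raw fluorescence is baseline 1.0 plus transients — an
    instantaneous rise of ``transient_amp`` decaying exponentially with
    ``decay_tau`` — at its background Poisson event frames and at the
    planted ensemble frames in which it participates (probability
    ``participation_p``), plus white Gaussian noise. Background and
    ensemble rates are scaled per epoch by ``condition_rate_ratios``.
    """
    if params.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(params.seed)
    fr = params.frame_rate
    n_frames = int(round(fr * (protocol.end - protocol.start)))
    if params.n_frames is not None and params.n_frames != n_frames:
        raise ValueError(
            f"n_frames={params.n_frames} inconsistent with protocol span "
            f"({n_frames} frames at {fr} frames/s)"
        )

    def epoch_frames(rate: float) -> np.ndarray:
        """Poisson event frames with per-epoch rate scaling."""
        frames = []
        for e in protocol.epochs:
            r = rate * params.condition_rate_ratios.get(e.label, 1.0)
            k = rng.poisson(r * e.duration)
            if k:
                tt = rng.uniform(e.start, e.end, size=k)
                frames.append(np.floor(tt * fr).astype(int))
        if not frames:
            return np.empty(0, dtype=int)
        out = np.unique(np.concatenate(frames))
        return out[out < n_frames]

    ensemble_frames = epoch_frames(params.ensemble_rate)
    cell_frames: list[np.ndarray] = []
    for _ in range(params.n_cells):
        bg = epoch_frames(params.bg_event_rate)
        take = rng.uniform(size=ensemble_frames.size) < params.participation_p
        cell_frames.append(np.unique(np.concatenate([bg, ensemble_frames[take]])))

    decay = np.exp(-1.0 / (params.decay_tau * fr))
    length = n_frames
    kernel = params.transient_amp * decay ** np.arange(length, dtype=float)
    traces = np.ones((params.n_cells, n_frames))
    for i, frames in enumerate(cell_frames):
        impulses = np.zeros(n_frames)
        np.add.at(impulses, frames, 1.0)
        traces[i] += np.convolve(impulses, kernel)[:n_frames]
    if params.noise_sd > 0:
        traces += rng.normal(0.0, params.noise_sd, traces.shape)

    truth = SimTruth(
        cell_event_frames=cell_frames,
        ensemble_frames=ensemble_frames,
        params=asdict(params),
        protocol=protocol,
    )
    return RawTraceSet(traces, fr), truth


# ---------------------------------------------------------------------------
# movie rendering


def render_movie(
    traces: RawTraceSet, params: CalciumSimParams, seed: int | None = None
) -> tuple[Movie, list[PlacedCell]]:
    """Render traces as a movie of disk-shaped somata on a dim background.

    Cells are placed as non-overlapping disks (uniform diameters in
    ``cell_diameter_range``) inside the field; each disk's pixel intensity
    follows ``cell_intensity × trace`` and the background sits at
    ``bg_intensity``, with Gaussian pixel noise. Returns the movie and the
    ground-truth centres/diameters.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    w_px = int(round(params.field_size[0] / params.pixel_size))
    h_px = int(round(params.field_size[1] / params.pixel_size))
    n_cells = traces.n_cells
    diameters = rng.uniform(*params.cell_diameter_range, size=n_cells)
    placed: list[PlacedCell] = []
    max_tries = 2000
    for i in range(n_cells):
        r_px = diameters[i] / 2 / params.pixel_size
        ok = False
        for _ in range(max_tries):
            r0 = rng.uniform(r_px + 1, h_px - r_px - 1)
            c0 = rng.uniform(r_px + 1, w_px - r_px - 1)
            sep_um = 2.0  # minimum edge-to-edge gap, μm
            if all(
                np.hypot(r0 - p.center[0], c0 - p.center[1]) * params.pixel_size
                >= (diameters[i] + p.diameter) / 2 + sep_um
                for p in placed
            ):
                placed.append(PlacedCell((r0, c0), diameters[i], i))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells "
                f"(placed {len(placed)})"
            )

    frames = np.full((traces.n_frames, h_px, w_px), params.bg_intensity)
    rr, cc = np.mgrid[:h_px, :w_px]
    for p in placed:
        r_px = p.diameter / 2 / params.pixel_size
        mask = (rr - p.center[0]) ** 2 + (cc - p.center[1]) ** 2 <= r_px**2
        frames[:, mask] = params.cell_intensity * traces.traces[p.index][:, None]
    if params.pixel_noise_sd > 0:
        frames += rng.normal(0.0, params.pixel_noise_sd, frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    return Movie(frames, traces.frame_rate, params.pixel_size), placed
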