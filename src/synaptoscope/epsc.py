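"""Spontaneous/miniature EPSC analysis on voltage-clamp current traces.

Events are inward (negative) current deflections recorded at a fixed holding
potential (−70 mV in the experiments this pipeline emulates). The analysis
chain mirrors standard practice for spontaneous-release pharmacology:

1. robust noise estimation per cell, so the detection threshold "exceeds
   noise values";
2. threshold-crossing peak detection with a local pre-event baseline;
3. 10-s-bin frequency (and amplitude) histograms;
4. normalization to the control-epoch baseline (percent of baseline);
5. a 5-min maximal-effect analysis window after drug onset;
6. burst detection (50–150 ms clusters of events);
7. per-cell responsiveness by Mann–Whitney U within 10 min of drug onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .protocol import DrugProtocol
from .stats import TestResult, mann_whitney_u

__all__ = [
    "CurrentTrace",
    "NoiseModel",
    "EventTrain",
    "BinnedSeries",
    "Burst",
    "estimate_noise",
    "detect_events",
    "bin_frequency",
    "bin_amplitude",
    "normalize_to_baseline",
    "select_effect_window",
    "detect_bursts",
    "responsive_cell",
    "cumulative_fraction",
]

_MAD_TO_SD = 1.4826  # consistency constant for Gaussian noise


# ---------------------------------------------------------------------------
# containers


@dataclass
class CurrentTrace:
    """A sampled holding-current record (pA) with acquisition metadata."""

    samples: np.ndarray  # pA
    sampling_rate: float  # Hz
    holding_potential: float = -70.0  # mV
    protocol: DrugProtocol | None = None
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class NoiseModel:
    sd: float  # pA
    method: str
    estimation_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class EventTrain:
    """Detected event peak times (s) and positive inward amplitudes (pA)."""

    times: np.ndarray
    amplitudes: np.ndarray
    cell_id: str = "cell"
    duration: float | None = None  # recording span the train was detected on

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive magnitudes")

    def __len__(self) -> int:
        return self.times.size

    def inter_event_intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class BinnedSeries:
    """Per-bin event frequency (Hz) or mean amplitude (pA)."""

    bin_edges: np.ndarray
    values: np.ndarray
    kind: str = "frequency"
    normalized: bool = False
    baseline_mean: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.bin_edges.size - 1:
            raise ValueError("need len(values) == len(bin_edges) - 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bins_in(self, start: float, end: float) -> np.ndarray:
        """Values of bins fully contained in [start, end]."""
        m = (self.bin_edges[:-1] >= start - 1e-9) & (self.bin_edges[1:] <= end + 1e-9)
        return self.values[m]


@dataclass
class Burst:
    """A short (50–150 ms) cluster of synaptic events.

    ``within_freq`` is the within-burst instantaneous frequency,
    (n_events − 1) / (end − start).
    """

    start: float
    end: float
    n_events: int
    within_freq: float

    def __post_init__(self) -> None:
        span = self.end - self.start
        if not (0.05 - 1e-9 <= span <= 0.15 + 1e-9):
            raise ValueError("burst span must lie in [50, 150] ms")
        if self.n_events < 3:
            raise ValueError("a burst needs at least 3 events")


# ---------------------------------------------------------------------------
# noise and event detection


def estimate_noise(
    trace: CurrentTrace, window: tuple[float, float] | None = None
) -> NoiseModel:
    """Robust baseline-noise SD over an (event-sparse) window.

    The trace is high-passed by first differencing, which removes the
    holding-current offset and slow drift; the noise SD is then
    MAD × 1.4826 / √2 of the differenced samples (the √2 undoes the
    variance doubling of differencing for white noise). The median absolute
    deviation keeps the estimate insensitive to the sparse synaptic events
    themselves.
    """
    if window is None:
        window = (0.0, trace.duration)
    lo, hi = window
    if not (0.0 <= lo < hi <= trace.duration + 1e-9):
        raise ValueError(f"window {window} outside trace of duration {trace.duration:.3f} s")
    i0 = int(round(lo * trace.sampling_rate))
    i1 = int(round(hi * trace.sampling_rate))
    seg = trace.samples[i0:i1]
    if seg.size < 2:
        raise ValueError("noise window too short")
    d = np.diff(seg)
    sd = _MAD_TO_SD * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    return NoiseModel(sd=sd, method="mad_of_first_difference", estimation_window=(lo, hi))


def detect_events(
    trace: CurrentTrace,
    noise: NoiseModel,
    k_threshold: float = 3.0,
    refractory: float = 2.0,
) -> EventTrain:
    """Detect inward synaptic events whose amplitude exceeds ``k × noise SD``.

    The trace is lightly smoothed (Gaussian, σ = 1 sample) and local inward
    peaks at least ``refractory`` ms apart are located. Each candidate's
    amplitude is measured from a local pre-event baseline — the median over
    the 2 ms ending 1 ms before the peak — to the peak; candidates with
    amplitude ≥ ``k_threshold × noise.sd`` are kept. Detection is
    deterministic and invariant to constant offsets.
    """
    if k_threshold <= 0:
        raise ValueError("k_threshold must be > 0")
    if not np.isfinite(noise.sd):
        raise ValueError("noise sd must be finite")
    fs = trace.sampling_rate
    x = gaussian_filter1d(trace.samples, sigma=1.0, mode="nearest")
    med = float(np.median(x))
    thr = k_threshold * noise.sd
    if thr <= 0:  # noiseless trace: any deflection is an event candidate
        thr = np.finfo(float).tiny
    dist = max(1, int(round(refractory * 1e-3 * fs)))
    # generous candidate pre-filter; the local-baseline amplitude decides
    peaks, _ = find_peaks(-(x - med), height=0.5 * thr, distance=dist)
    if peaks.size == 0:
        return EventTrain(np.empty(0), np.empty(0), trace.cell_id, trace.duration)

    pre_gap = max(1, int(round(1e-3 * fs)))  # end baseline 1 ms before peak
    pre_len = max(1, int(round(2e-3 * fs)))  # 2 ms of local baseline
    times, amps = [], []
    for p in peaks:
        b1 = p - pre_gap
        b0 = b1 - pre_len
        if b0 < 0:
            b0, b1 = 0, max(1, b1)
        if b1 <= b0:
            continue
        baseline = float(np.median(x[b0:b1]))
        amp = baseline - x[p]  # inward deflection as positive pA
        if amp >= thr:
            times.append(p / fs)
            amps.append(amp)
    return EventTrain(np.array(times), np.array(amps), trace.cell_id, trace.duration)


# ---------------------------------------------------------------------------
# binning and normalization


def _train_duration(train: EventTrain, duration: float | None) -> float:
    if duration is not None:
        return duration
    if train.duration is not None:
        return train.duration
    if len(train) == 0:
        raise ValueError("cannot infer duration from an empty train")
    return float(train.times[-1])


def bin_frequency(
    train: EventTrain, bin_width: float = 10.0, duration: float | None = None
) -> BinnedSeries:
    """Event frequency (Hz) in consecutive bins; the last partial bin is dropped."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    total = _train_duration(train, duration)
    n_bins = int(np.floor(total / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    return BinnedSeries(edges, counts / bin_width, kind="frequency")


def bin_amplitude(
    train: EventTrain, bin_width: float = 10.0, duration: float | None = None
) -> BinnedSeries:
    """Mean event amplitude (pA) per bin; empty bins are NaN."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    total = _train_duration(train, duration)
    n_bins = int(np.floor(total / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    sums, _ = np.histogram(train.times, bins=edges, weights=train.amplitudes)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedSeries(edges, means, kind="amplitude")


def normalize_to_baseline(series: BinnedSeries, protocol: DrugProtocol) -> BinnedSeries:
    """Express bins as percent of the control-epoch mean (baseline = 100%)."""
    ctrl = protocol.control
    base = series.bins_in(ctrl.start, ctrl.end)
    base = base[np.isfinite(base)]
    if base.size < 3:
        raise ValueError("control epoch must contain at least 3 bins")
    mean = float(np.mean(base))
    if mean == 0:
        raise ValueError(
            "control-epoch mean is zero; cannot normalize "
            f"({base.size} control bins, all zero)"
        )
    return BinnedSeries(
        series.bin_edges,
        100.0 * series.values / mean,
        kind=series.kind,
        normalized=True,
        baseline_mean=mean,
    )


def select_effect_window(
    series: BinnedSeries, protocol: DrugProtocol, width: float = 300.0
) -> tuple[float, float]:
    """The ``width``-long window after drug onset maximizing the mean value.

    Candidate windows are aligned to bin edges, start at or after drug
    onset, and span ``width`` seconds (default 5 min). Ties break to the
    earliest window.
    """
    onset = protocol.drug_onset
    edges = series.bin_edges
    bw = edges[1] - edges[0]
    n_win = int(round(width / bw))
    if n_win < 1:
        raise ValueError("window narrower than one bin")
    starts = [i for i in range(edges.size - 1) if edges[i] >= onset - 1e-9]
    starts = [i for i in starts if i + n_win <= series.values.size]
    if not starts:
        raise ValueError(
            f"insufficient post-onset data for a {width:.0f}-s window"
        )
    best_i, best_mean = None, -np.inf
    for i in starts:
        seg = series.values[i : i + n_win]
        m = float(np.nanmean(seg)) if np.any(np.isfinite(seg)) else -np.inf
        if m > best_mean + 1e-12:
            best_i, best_mean = i, m
    if best_i is None:
        raise ValueError("no finite bins after drug onset")
    return float(edges[best_i]), float(edges[best_i] + n_win * bw)


# ---------------------------------------------------------------------------
# bursts


def detect_bursts(
    train: EventTrain,
    baseline_freq: float,
    min_events: int = 3,
    span_range: tuple[float, float] = (0.05, 0.15),
    rate_factor: float = 1.5,
) -> list[Burst]:
    """Detect 50–150 ms clusters of events (bursts of synchronized release).

    A burst is a maximal run of at least ``min_events`` consecutive events
    whose total span lies in ``span_range`` and whose within-run frequency
    (n − 1)/span is at least ``rate_factor`` × ``baseline_freq``. Runs are
    grown greedily from the earliest unconsumed event, so overlapping
    candidates merge into the maximal run.
    """
    if baseline_freq <= 0:
        raise ValueError("baseline_freq must be > 0")
    t = train.times
    lo, hi = span_range
    bursts: list[Burst] = []
    i = 0
    n = t.size
    while i < n:
        # longest run starting at i with span <= hi
        j = i
        while j + 1 < n and t[j + 1] - t[i] <= hi:
            j += 1
        count = j - i + 1
        span = t[j] - t[i]
        if count >= min_events and span >= lo:
            freq = (count - 1) / span
            if freq >= rate_factor * baseline_freq:
                bursts.append(Burst(float(t[i]), float(t[j]), int(count), float(freq)))
                i = j + 1
                continue
        i += 1
    return bursts


# ---------------------------------------------------------------------------
# responsiveness and distributions


def responsive_cell(
    series: BinnedSeries,
    protocol: DrugProtocol,
    alpha: float = 0.05,
    response_window: float = 600.0,
) -> tuple[bool, TestResult]:
    """Was there a significant change within 10 min of drug administration?

    Two-sided Mann–Whitney U between control-epoch bins and the bins in the
    first ``response_window`` seconds (default 10 min) after drug onset.
    """
    ctrl = protocol.control
    control_bins = series.bins_in(ctrl.start, ctrl.end)
    onset = protocol.drug_onset
    post_bins = series.bins_in(onset, onset + response_window)
    control_bins = control_bins[np.isfinite(control_bins)]
    post_bins = post_bins[np.isfinite(post_bins)]
    if control_bins.size < 3 or post_bins.size < 3:
        raise ValueError("need at least 3 control bins and 3 post-onset bins")
    res = mann_whitney_u(control_bins, post_bins)
    return bool(res.p_value < alpha), res


def cumulative_fraction(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative fractions ending at 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cumulative_fraction needs a non-empty sample")
    v = np.sort(v)
    frac = np.arange(1, v.size + 1) / v.size
    return v, frac
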