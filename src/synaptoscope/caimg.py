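"""Calcium-imaging population analysis.

From a fluorescence movie (or per-ROI traces) to ΔF/F transients, a binary
cells × frames activity raster, a coactivity histogram, and Monte
Carlo–validated synchrony peaks, plus per-cell activity comparisons across
experimental conditions.

The imaging model follows bulk-loaded indicator recordings of a small
brainstem field: a few dozen somata of 4–30 μm diameter imaged at 4
frames/s, where a calcium transient (fast rise, ~1–2 s decay) marks a
firing episode. Activity is marked at transient onsets only, because the
first derivative of the fluorescence — not its sustained elevation — is the
firing indicator; marking whole transient durations would inflate
coactivity at this slow decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks
from skimage.feature import peak_local_max

from .protocol import CONDITIONS
from .stats import friedman, ks_two_sample

__all__ = [
    "Movie",
    "Roi",
    "RoiMap",
    "RawTraceSet",
    "DffTraceSet",
    "TransientSet",
    "BinaryRaster",
    "CoactivityResult",
    "CellActivitySummary",
    "extract_rois",
    "roi_traces",
    "compute_dff",
    "detect_transients",
    "binarize",
    "coactivity",
    "monte_carlo_threshold",
    "cell_activity",
    "compare_activity",
]

_MAD_TO_SD = 1.4826


# ---------------------------------------------------------------------------
# containers


@dataclass
class Movie:
    """A fluorescence image stack (frame, row, col)."""

    frames: np.ndarray
    frame_rate: float  # frames/s
    pixel_size: float = 1.0  # μm/px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("movie must be a 3-D (frame, row, col) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class Roi:
    center: tuple[float, float]  # (row, col) px
    diameter: float  # μm
    id: int


@dataclass
class RoiMap:
    rois: list[Roi]
    summary_image: np.ndarray
    pixel_size: float = 1.0

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class RawTraceSet:
    """Per-cell raw fluorescence traces (a.u.), before ΔF/F normalization."""

    traces: np.ndarray  # cells × frames
    frame_rate: float
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.traces.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class DffTraceSet:
    """ΔF/F = (F_t − F0) / F0 traces with the per-cell resting fluorescence F0."""

    traces: np.ndarray  # cells × frames, dimensionless
    f0: np.ndarray  # per-cell resting fluorescence, a.u.
    frame_rate: float
    cell_ids: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # cells rejected (F0 <= 0)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.f0 = np.atleast_1d(np.asarray(self.f0, dtype=float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("ΔF/F traces must be finite")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.traces.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class TransientSet:
    """Per-cell transient onset frames with peak ΔF/F amplitudes."""

    onsets: list[np.ndarray]  # frame indices, per cell
    amplitudes: list[np.ndarray]  # peak ΔF/F above baseline, per cell
    noise_sd: np.ndarray  # per-cell ΔF/F noise SD estimate
    amp_threshold: np.ndarray  # per-cell acceptance threshold (k_amp × noise_sd)
    frame_rate: float
    n_frames: int


@dataclass
class BinaryRaster:
    """Cells × frames 0/1 matrix; 1 marks an activity onset."""

    matrix: np.ndarray
    frame_rate: float
    condition_of_frame: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix))
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("raster must contain only 0/1")
        self.matrix = self.matrix.astype(np.uint8)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CoactivityResult:
    coactivity: np.ndarray  # per-frame count of simultaneously active cells
    threshold: int
    n_surrogates: int
    significant_frames: np.ndarray
    surrogate_scheme: str
    surrogate_max: np.ndarray | None = None  # per-surrogate maximum coactivity
    seed: int | None = None


@dataclass
class CellActivitySummary:
    """Active-frame counts and fractions per cell × condition."""

    conditions: list[str]
    counts: np.ndarray  # cells × conditions
    fractions: np.ndarray  # cells × conditions, active frames / frames in condition
    frames_per_condition: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("activity fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ROI extraction and trace collection


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return _MAD_TO_SD * float(np.median(np.abs(values - med)))


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def extract_rois(
    movie: Movie,
    diameter_range: tuple[float, float] = (4.0, 30.0),
    smooth_px: float = 1.0,
    prominence_mads: float = 5.0,
) -> RoiMap:
    """Place circular ROIs on active cells from the temporal-SD summary image.

    The summary image is the per-pixel temporal standard deviation, which
    highlights pixels whose fluorescence fluctuates (active somata) and is
    flat for static structures. Candidate centres are local maxima of the
    lightly smoothed summary image above a robust prominence floor
    (median + ``prominence_mads`` × MAD); each candidate is fitted with the
    disk diameter in ``diameter_range`` maximizing the disk-minus-annulus
    contrast, and candidates are accepted greedily in decreasing peak order
    with no overlap.
    """
    lo, hi = diameter_range
    if not (4.0 <= lo < hi <= 30.0):
        raise ValueError("diameter_range must lie within [4, 30] μm")
    if movie.n_frames < 10:
        raise ValueError("need at least 10 frames to build a summary image")
    summary = movie.frames.std(axis=0)
    smoothed = gaussian_filter(summary, smooth_px)
    floor = float(np.median(smoothed) + prominence_mads * _robust_sd(smoothed))
    min_dist = max(1, int(round(lo / movie.pixel_size / 2)))
    peaks = peak_local_max(
        smoothed, min_distance=min_dist, threshold_abs=floor + np.finfo(float).tiny
    )
    order = np.argsort(-smoothed[tuple(peaks.T)]) if peaks.size else []
    radii_um = np.arange(lo / 2, hi / 2 + 0.25, 0.5)
    accepted: list[Roi] = []
    shape = movie.shape
    rr_g, cc_g = np.mgrid[: shape[0], : shape[1]]
    excess = np.clip(smoothed - floor, 0.0, None)
    for k in order:
        r0, c0 = (float(v) for v in peaks[k])
        # a uniform soma gives a flat SD plateau, so the raw peak can land
        # anywhere on it; two mean-shift steps of the supra-floor mass pull
        # the centre onto the blob centroid
        for _ in range(2):
            win = (rr_g - r0) ** 2 + (cc_g - c0) ** 2 <= (hi / 2 / movie.pixel_size) ** 2
            w = excess[win]
            if w.sum() <= 0:
                break
            r0 = float(np.average(rr_g[win], weights=w))
            c0 = float(np.average(cc_g[win], weights=w))
        best_r, best_score = None, -np.inf
        for r_um in radii_um:
            r_px = r_um / movie.pixel_size
            if (
                r0 - r_px < 0
                or c0 - r_px < 0
                or r0 + r_px > shape[0] - 1
                or c0 + r_px > shape[1] - 1
            ):
                continue
            disk = _disk_mask(shape, (r0, c0), r_px)
            ann = _disk_mask(shape, (r0, c0), min(r_px + 2, r_px * 1.6)) & ~disk
            if not ann.any():
                continue
            score = float(summary[disk].mean() - summary[ann].mean())
            if score > best_score:
                best_score, best_r = score, r_um
        if best_r is None:
            continue
        r_px = best_r / movie.pixel_size
        overlap = any(
            np.hypot(r0 - a.center[0], c0 - a.center[1]) * movie.pixel_size
            < (best_r + a.diameter / 2)
            for a in accepted
        )
        if not overlap:
            accepted.append(Roi((float(r0), float(c0)), 2 * best_r, len(accepted)))
    return RoiMap(accepted, summary, movie.pixel_size)


def roi_traces(movie: Movie, rois: RoiMap) -> RawTraceSet:
    """Mean pixel intensity per frame over each ROI disk."""
    shape = movie.shape
    traces = np.empty((len(rois.rois), movie.n_frames))
    for i, roi in enumerate(rois.rois):
        r_px = roi.diameter / 2 / movie.pixel_size
        r0, c0 = roi.center
        if r0 - r_px < -0.5 or c0 - r_px < -0.5 or r0 + r_px > shape[0] - 0.5 or c0 + r_px > shape[1] - 0.5:
            raise ValueError(f"ROI {roi.id} extends outside the imaged field")
        mask = _disk_mask(shape, roi.center, r_px)
        traces[i] = movie.frames[:, mask].mean(axis=1)
    if len(rois.rois) == 0:
        traces = np.empty((0, movie.n_frames))
    return RawTraceSet(traces, movie.frame_rate, [f"roi{r.id}" for r in rois.rois])


# ---------------------------------------------------------------------------
# ΔF/F and transient detection


def compute_dff(
    raw: RawTraceSet, f0_method: str = "percentile", f0_percentile: float = 10.0
) -> DffTraceSet:
    """ΔF/F = (F_t − F0)/F0 with F0 = a low percentile of each raw trace.

    The 10th percentile resists contamination of the resting-fluorescence
    estimate by the transients themselves. Cells with F0 ≤ 0 cannot be
    normalized and are excluded (recorded in ``excluded``). ΔF/F is
    invariant under multiplicative illumination gain.
    """
    if f0_method != "percentile":
        raise ValueError(f"unknown f0_method {f0_method!r}")
    f0 = np.percentile(raw.traces, f0_percentile, axis=1) if raw.n_cells else np.empty(0)
    good = f0 > 0
    excluded = [cid for cid, ok in zip(raw.cell_ids, good) if not ok]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} cell(s) with non-positive F0: {excluded}"
        )
    traces = (raw.traces[good] - f0[good, None]) / f0[good, None]
    ids = [cid for cid, ok in zip(raw.cell_ids, good) if ok]
    return DffTraceSet(traces.reshape(int(good.sum()), raw.n_frames), f0[good],
                       raw.frame_rate, ids, excluded)


def _masked_noise_sd(x: np.ndarray, k: float) -> float:
    """Robust SD of a trace's noise: MAD around the median, with one
    iteration of masking provisional supra-threshold frames."""
    med = np.median(x)
    sd = _MAD_TO_SD * float(np.median(np.abs(x - med)))
    if sd > 0:
        keep = np.abs(x - med) < k * sd
        if keep.sum() >= 8:
            med = np.median(x[keep])
            sd = _MAD_TO_SD * float(np.median(np.abs(x[keep] - med)))
    return sd


def detect_transients(
    dff: DffTraceSet,
    k_amp: float = 2.5,
    k_deriv: float = 2.5,
    peak_window: int = 6,
) -> TransientSet:
    """Detect calcium-transient onsets per cell.

    A transient is an abrupt fluorescence rise followed by a supra-threshold
    peak. For each cell, with robust noise SD σ (MAD with one masking
    iteration):

    * the rise statistic r_t = (x_{t+1} + x_t − x_{t−1} − x_{t−2}) / 2 — a
      two-frame first difference whose noise SD equals σ for white noise —
      must exceed ``k_deriv`` × its own robustly estimated SD, and
    * the following ΔF/F peak (within ``peak_window`` frames, measured above
      the cell's median baseline) must reach ``k_amp`` × σ.

    Onsets are the local maxima of the rise statistic (with a prominence
    floor equal to the rise threshold, so chance wiggles inside one genuine
    rise do not split it), which localizes each onset to ±1 frame for
    step-like transients; events closer than ~2 frames are not resolvable
    at this frame rate. The acceptance threshold ``k_amp × σ`` is reported
    per cell.
    """
    if dff.n_frames < 8:
        raise ValueError("need at least 8 frames to detect transients")
    onsets: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    noise_sds = np.empty(dff.n_cells)
    thresholds = np.empty(dff.n_cells)
    for i in range(dff.n_cells):
        x = dff.traces[i]
        sd = _masked_noise_sd(x, k_amp)
        noise_sds[i] = sd
        thresholds[i] = k_amp * sd
        if sd == 0:
            # noiseless trace: any strictly positive rise marks an onset
            rise_thr = np.finfo(float).tiny
            amp_thr = np.finfo(float).tiny
        else:
            rise_thr = None
            amp_thr = k_amp * sd
        r = np.full(x.size, -np.inf)
        r[2:-1] = 0.5 * (x[3:] + x[2:-1] - x[1:-2] - x[:-3])
        finite_r = r[2:-1]
        if rise_thr is None:
            sd_r = _masked_noise_sd(finite_r, k_deriv)
            rise_thr = k_deriv * sd_r if sd_r > 0 else np.finfo(float).tiny
        baseline = float(np.median(x))
        n = x.size
        r_finite = np.where(np.isfinite(r), r, -1e30)
        # each transient produces one local maximum of the rise statistic;
        # the prominence floor keeps chance wiggles inside a genuine rise
        # from splitting it
        cand, _ = find_peaks(r_finite, height=rise_thr, prominence=rise_thr)
        cell_onsets, cell_amps = [], []
        for onset in cand:
            p_end = min(n, onset + peak_window)
            peak = float(np.max(x[onset:p_end]) - baseline)
            if peak >= amp_thr:
                cell_onsets.append(int(onset))
                cell_amps.append(peak)
        onsets.append(np.array(cell_onsets, dtype=int))
        amps.append(np.array(cell_amps))
    return TransientSet(onsets, amps, noise_sds, thresholds, dff.frame_rate, dff.n_frames)


# ---------------------------------------------------------------------------
# raster, coactivity, surrogates


def binarize(
    transients: TransientSet,
    n_frames: int | None = None,
    condition_of_frame: list[str | None] | None = None,
) -> BinaryRaster:
    """Binary raster with 1 exactly at each cell's transient onset frames."""
    n_frames = transients.n_frames if n_frames is None else n_frames
    mat = np.zeros((len(transients.onsets), n_frames), dtype=np.uint8)
    for i, cell_onsets in enumerate(transients.onsets):
        if cell_onsets.size and cell_onsets.max() >= n_frames:
            raise ValueError("onset frame beyond raster length")
        if cell_onsets.size != np.unique(cell_onsets).size:
            warnings.warn(f"cell {i}: duplicate onsets collapsed")
        mat[i, cell_onsets] = 1
    return BinaryRaster(mat, transients.frame_rate, condition_of_frame)


def coactivity(raster: BinaryRaster) -> np.ndarray:
    """Per-frame count of simultaneously active cells (column sums)."""
    if raster.matrix.size == 0:
        raise ValueError("empty raster")
    return raster.matrix.sum(axis=0).astype(int)


def monte_carlo_threshold(
    raster: BinaryRaster,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CoactivityResult:
    """Significance threshold for coactivity peaks from circular-shift surrogates.

    Each surrogate independently circularly shifts every cell's row by a
    uniform random offset, preserving per-cell event counts and within-cell
    timing structure while destroying across-cell alignment. The
    per-surrogate maximum coactivity builds a family-wise null for peaks;
    the threshold is the smallest integer count reached by fewer than
    ``alpha × n_surrogates`` surrogates. Frames whose observed coactivity
    meets the threshold are the significant synchrony peaks.
    """
    if raster.n_frames < 10:
        raise ValueError("need at least 10 frames")
    if n_surrogates < 100:
        warnings.warn("fewer than 100 surrogates gives a coarse null")
    obs = coactivity(raster)
    if raster.n_cells < 2:
        return CoactivityResult(
            obs, raster.n_cells + 1, n_surrogates, np.empty(0, dtype=int),
            "circular_shift", None, seed,
        )
    rng = np.random.default_rng(seed)
    T = raster.n_frames
    rows = [np.flatnonzero(raster.matrix[i]) for i in range(raster.n_cells)]
    events = np.concatenate([r for r in rows]) if any(r.size for r in rows) else np.empty(0, int)
    cell_of_event = np.concatenate(
        [np.full(r.size, i) for i, r in enumerate(rows)]
    ) if events.size else np.empty(0, int)
    offsets = rng.integers(0, T, size=(n_surrogates, raster.n_cells))
    maxima = np.zeros(n_surrogates, dtype=int)
    if events.size:
        # one bincount per surrogate over the shifted event frames
        shifted = (events[None, :] + offsets[:, cell_of_event]) % T
        flat = (shifted + (np.arange(n_surrogates)[:, None] * T)).ravel()
        counts = np.bincount(flat, minlength=n_surrogates * T).reshape(n_surrogates, T)
        maxima = counts.max(axis=1)
    if alpha >= 1.0:
        threshold = 1  # degenerate bound: any coactive frame is "significant"
    else:
        threshold = raster.n_cells + 1
        for c in range(0, raster.n_cells + 2):
            if np.sum(maxima >= c) < alpha * n_surrogates:
                threshold = c
                break
    sig = np.flatnonzero(obs >= threshold)
    return CoactivityResult(
        obs, int(threshold), n_surrogates, sig, "circular_shift", maxima, seed
    )


# ---------------------------------------------------------------------------
# per-cell activity across conditions


def cell_activity(raster: BinaryRaster) -> CellActivitySummary:
    """Active-frame count and fraction per cell in each condition."""
    if raster.condition_of_frame is None:
        raise ValueError("raster has no per-frame condition labels")
    labels = raster.condition_of_frame
    if any(l is None for l in labels):
        raise ValueError("all frames must carry a condition label")
    conditions = [c for c in CONDITIONS if c in labels]
    counts = np.zeros((raster.n_cells, len(conditions)), dtype=int)
    frames = np.zeros(len(conditions), dtype=int)
    lab_arr = np.array(labels)
    for j, cond in enumerate(conditions):
        m = lab_arr == cond
        frames[j] = int(m.sum())
        counts[:, j] = raster.matrix[:, m].sum(axis=1)
    fractions = counts / np.maximum(frames, 1)
    return CellActivitySummary(conditions, counts, fractions, frames)


def compare_activity(summary: CellActivitySummary, use: str = "fractions") -> dict:
    """Condition comparisons of per-cell activity.

    Pairwise two-sample KS tests of the activity distributions against
    control, and a Friedman test across the paired per-cell condition
    triplets.
    """
    if len(summary.conditions) < 3:
        raise ValueError("need the three conditions (control/drug/wash)")
    data = summary.fractions if use == "fractions" else summary.counts.astype(float)
    if data.shape[0] < 5:
        raise ValueError("need at least 5 cells")
    cond_idx = {c: i for i, c in enumerate(summary.conditions)}
    ks = {}
    for cond in summary.conditions:
        if cond == "control":
            continue
        ks[f"control_vs_{cond}"] = ks_two_sample(
            data[:, cond_idx["control"]], data[:, cond_idx[cond]]
        )
    fr = friedman(data)
    return {"ks": ks, "friedman": fr, "measure": use}
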