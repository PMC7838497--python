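"""ROI extraction, ΔF/F, transients, raster, coactivity, condition tests."""

import numpy as np
import pytest

from oracles import friedman_stat_brute, match_events
from synaptoscope import control_only_protocol, three_stage_protocol
from synaptoscope.caimg import (
    BinaryRaster,
    DffTraceSet,
    Movie,
    RawTraceSet,
    TransientSet,
    binarize,
    cell_activity,
    coactivity,
    compare_activity,
    compute_dff,
    detect_transients,
    extract_rois,
    monte_carlo_threshold,
    roi_traces,
)
from synaptoscope.synth import CalciumSimParams, render_movie, simulate_calcium_traces

FR = 4.0


def dff_of(rows):
    rows = np.atleast_2d(np.asarray(rows, float))
    return DffTraceSet(rows, np.ones(rows.shape[0]), FR)


def plant_transients(n_frames, frames, amp, tau_frames=6.0, noise_sd=0.0, rng=None):
    imp = np.zeros(n_frames)
    imp[np.asarray(frames, int)] = 1.0
    kern = amp * np.exp(-np.arange(n_frames) / tau_frames)
    x = np.convolve(imp, kern)[:n_frames]
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n_frames)
    return x


class TestRois:
    def test_noise_only_movie_has_no_rois(self, rng):
        frames = rng.normal(100, 2, (120, 80, 80)).clip(0)
        rois = extract_rois(Movie(frames, FR))
        assert len(rois) == 0

    def test_rendered_cells_recovered_within_two_px(self):
        proto = control_only_protocol(60.0)
        params = CalciumSimParams(n_cells=5, bg_event_rate=0.2, noise_sd=0.01,
                                  pixel_noise_sd=1.0, field_size=(150.0, 150.0),
                                  cell_diameter_range=(10.0, 16.0), seed=3)
        traces, _ = simulate_calcium_traces(params, proto)
        movie, cells = render_movie(traces, params)
        rois = extract_rois(movie)
        assert len(rois) == 5
        truth = np.array([c.center for c in cells])
        for roi in rois.rois:
            d = np.min(np.hypot(*(truth - np.array(roi.center)).T))
            assert d <= 2.0

    def test_static_bright_disk_ignored(self):
        frames = np.full((50, 60, 60), 100.0)
        rr, cc = np.mgrid[:60, :60]
        frames[:, (rr - 30) ** 2 + (cc - 30) ** 2 <= 36] = 400.0
        assert len(extract_rois(Movie(frames, FR))) == 0

    def test_bad_diameter_range_rejected(self):
        movie = Movie(np.zeros((20, 40, 40)), FR)
        with pytest.raises(ValueError):
            extract_rois(movie, diameter_range=(1.0, 40.0))


class TestRoiTraces:
    def test_uniform_movie_gives_constant_traces(self):
        from synaptoscope.caimg import Roi, RoiMap

        movie = Movie(np.full((30, 50, 50), 7.0), FR)
        rois = RoiMap([Roi((25.0, 25.0), 10.0, 0)], np.zeros((50, 50)))
        traces = roi_traces(movie, rois)
        assert np.allclose(traces.traces, 7.0)

    def test_rendered_traces_correlate_with_source(self):
        proto = control_only_protocol(60.0)
        params = CalciumSimParams(n_cells=3, bg_event_rate=0.2, noise_sd=0.0,
                                  pixel_noise_sd=0.0, field_size=(120.0, 120.0),
                                  cell_diameter_range=(10.0, 14.0), seed=5)
        traces, _ = simulate_calcium_traces(params, proto)
        movie, cells = render_movie(traces, params)
        rois = extract_rois(movie)
        got = roi_traces(movie, rois)
        for i in range(got.n_cells):
            corrs = [
                np.corrcoef(got.traces[i], traces.traces[j])[0, 1] for j in range(3)
            ]
            assert max(corrs) > 0.99

    def test_roi_outside_field_rejected(self):
        from synaptoscope.caimg import Roi, RoiMap

        movie = Movie(np.zeros((30, 50, 50)), FR)
        rois = RoiMap([Roi((48.0, 48.0), 10.0, 0)], np.zeros((50, 50)))
        with pytest.raises(ValueError):
            roi_traces(movie, rois)

    def test_no_rois_empty_set(self):
        from synaptoscope.caimg import RoiMap

        movie = Movie(np.zeros((30, 50, 50)), FR)
        assert roi_traces(movie, RoiMap([], np.zeros((50, 50)))).n_cells == 0


class TestDff:
    def test_constant_trace_gives_zero_dff(self):
        raw = RawTraceSet(np.full((1, 100), 50.0), FR)
        dff = compute_dff(raw)
        assert np.allclose(dff.traces, 0.0)

    def test_doubling_step_gives_unit_peak(self):
        x = np.full(100, 10.0)
        x[60:] = 20.0
        dff = compute_dff(RawTraceSet(x[None, :], FR))
        assert dff.traces.max() == pytest.approx(1.0)

    def test_gain_invariance(self, rng):
        x = 100 + rng.normal(0, 3, (4, 200)).cumsum(axis=1) * 0.01 + 10
        a = compute_dff(RawTraceSet(x, FR))
        b = compute_dff(RawTraceSet(3.7 * x, FR))
        assert np.allclose(a.traces, b.traces)

    def test_nonpositive_f0_cell_excluded_with_warning(self):
        x = np.vstack([np.full(100, 10.0), np.full(100, -1.0)])
        with pytest.warns(UserWarning, match="non-positive F0"):
            dff = compute_dff(RawTraceSet(x, FR))
        assert dff.n_cells == 1
        assert dff.excluded == ["cell1"]


class TestTransients:
    def test_flat_trace_has_no_transients(self):
        res = detect_transients(dff_of(np.zeros(200)))
        assert res.onsets[0].size == 0

    def test_recall_and_onset_accuracy_at_5_sigma(self, rng):
        sigma = 0.03
        tp = fn = fp = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            frames = np.arange(20, 1400, 45)
            x = plant_transients(1440, frames, 5 * sigma, noise_sd=sigma, rng=r)
            res = detect_transients(dff_of(x))
            a, b, c = match_events(frames, res.onsets[0], 1)
            tp, fn, fp = tp + a, fn + b, fp + c
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_pure_noise_false_rate_below_gaussian_tail_bound(self):
        from scipy.stats import norm

        n_fp, n_frames = 0, 0
        for seed in range(30):
            x = np.random.default_rng(seed).normal(0, 0.03, 1440)
            res = detect_transients(dff_of(x))
            n_fp += res.onsets[0].size
            n_frames += 1440
        assert n_fp / n_frames < norm.sf(2.5)

    def test_amp_threshold_is_k_times_noise_sd(self, rng):
        x = rng.normal(0, 0.03, 2000)
        res = detect_transients(dff_of(x), k_amp=2.5)
        assert res.amp_threshold[0] == pytest.approx(2.5 * res.noise_sd[0])
        assert res.noise_sd[0] == pytest.approx(0.03, rel=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_transients(dff_of(np.zeros(5)))


class TestRasterCoactivity:
    def test_binarize_marks_onsets_only(self):
        tr = TransientSet([np.array([3, 10])], [np.ones(2)], np.zeros(1), np.zeros(1),
                          FR, 20)
        raster = binarize(tr)
        assert raster.matrix.sum() == 2
        assert raster.matrix[0, 3] == 1 and raster.matrix[0, 10] == 1

    def test_noiseless_generator_raster_equals_truth(self):
        proto = control_only_protocol(360.0)
        params = CalciumSimParams(n_cells=6, bg_event_rate=0.05, ensemble_rate=0.01,
                                  noise_sd=0.0, seed=7)
        traces, truth = simulate_calcium_traces(params, proto)
        dff = compute_dff(traces)
        res = detect_transients(dff)
        raster = binarize(res)
        expect = np.zeros_like(raster.matrix)
        for i, frames in enumerate(truth.cell_event_frames):
            # events separated by <3 frames are below the 4 frames/s
            # temporal resolution and merge into the first onset
            keep = np.concatenate([[True], np.diff(frames) >= 3])
            expect[i, frames[keep]] = 1
        assert np.array_equal(raster.matrix, expect)

    def test_coactivity_is_column_sum(self, rng):
        mat = (rng.uniform(size=(7, 50)) < 0.2).astype(np.uint8)
        co = coactivity(BinaryRaster(mat, FR))
        brute = [sum(mat[i, f] for i in range(7)) for f in range(50)]
        assert co.tolist() == brute

    def test_three_cells_one_frame(self):
        mat = np.zeros((3, 20), dtype=np.uint8)
        mat[:, 7] = 1
        co = coactivity(BinaryRaster(mat, FR))
        assert co[7] == 3 and co.sum() == 3


class TestMonteCarlo:
    def test_all_zero_raster_has_no_significant_frames(self):
        res = monte_carlo_threshold(BinaryRaster(np.zeros((5, 100)), FR), 200, seed=0)
        assert res.significant_frames.size == 0

    def test_surrogates_preserve_row_sums(self, rng):
        # re-run the scheme by hand: shifting preserves per-cell counts
        mat = (rng.uniform(size=(6, 80)) < 0.15).astype(np.uint8)
        row_sums = mat.sum(axis=1)
        g = np.random.default_rng(0)
        for _ in range(50):
            surr = np.vstack(
                [np.roll(mat[i], g.integers(0, 80)) for i in range(6)]
            )
            assert np.array_equal(surr.sum(axis=1), row_sums)

    def test_planted_ensembles_flagged_exactly(self, rng):
        n_cells, T = 30, 1440
        mat = (rng.uniform(size=(n_cells, T)) < 0.005).astype(np.uint8)
        planted = np.array([200, 500, 800, 1100, 1400])
        for f in planted:
            part = rng.uniform(size=n_cells) < 0.6
            mat[part, f] = 1
        res = monte_carlo_threshold(BinaryRaster(mat, FR), 1000, 0.05, seed=3)
        assert res.surrogate_max.size == 1000
        assert np.array_equal(res.significant_frames, planted)

    def test_reproducible_given_seed(self, rng):
        mat = (rng.uniform(size=(10, 200)) < 0.1).astype(np.uint8)
        a = monte_carlo_threshold(BinaryRaster(mat, FR), 300, seed=5)
        b = monte_carlo_threshold(BinaryRaster(mat, FR), 300, seed=5)
        assert a.threshold == b.threshold
        assert np.array_equal(a.surrogate_max, b.surrogate_max)

    def test_single_cell_returns_no_significance(self):
        mat = np.ones((1, 50), dtype=np.uint8)
        res = monte_carlo_threshold(BinaryRaster(mat, FR), 200, seed=0)
        assert res.significant_frames.size == 0

    def test_denser_raster_does_not_lower_threshold(self, rng):
        base = (rng.uniform(size=(15, 400)) < 0.05).astype(np.uint8)
        extra = base | (rng.uniform(size=(15, 400)) < 0.10).astype(np.uint8)
        t1 = monte_carlo_threshold(BinaryRaster(base, FR), 400, seed=1).threshold
        t2 = monte_carlo_threshold(BinaryRaster(extra, FR), 400, seed=1).threshold
        assert t2 >= t1


class TestCellActivity:
    def _raster(self, mat, protocol):
        labels = protocol.condition_of_frame(mat.shape[1], FR)
        return BinaryRaster(mat, FR, labels)

    def test_all_zero_raster_all_fractions_zero(self):
        proto = three_stage_protocol(30, 30, 30)
        summary = cell_activity(self._raster(np.zeros((4, 360)), proto))
        assert np.all(summary.fractions == 0)

    def test_always_active_cell_fraction_one_everywhere(self):
        proto = three_stage_protocol(30, 30, 30)
        summary = cell_activity(self._raster(np.ones((1, 360)), proto))
        assert np.all(summary.fractions == 1.0)

    def test_rate_ratio_reflected_in_activity_fractions(self):
        proto = three_stage_protocol(600, 600, 600)
        params = CalciumSimParams(
            n_cells=30, bg_event_rate=0.05, ensemble_rate=0.0, noise_sd=0.0,
            condition_rate_ratios={"control": 1.0, "drug": 2.0, "wash": 1.0},
        )
        ratios = []
        for seed in range(5):
            traces, _ = simulate_calcium_traces(
                CalciumSimParams(**{**params.__dict__, "seed": seed}), proto
            )
            raster = binarize(
                detect_transients(compute_dff(traces)),
                condition_of_frame=proto.condition_of_frame(traces.n_frames, FR),
            )
            s = cell_activity(raster)
            i_ctrl = s.conditions.index("control")
            i_drug = s.conditions.index("drug")
            ratios.append(s.counts[:, i_drug].sum() / s.counts[:, i_ctrl].sum())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.2)

    def test_unlabeled_frames_rejected(self):
        raster = BinaryRaster(np.zeros((2, 10)), FR, ["control"] * 5 + [None] * 5)
        with pytest.raises(ValueError):
            cell_activity(raster)


class TestCompareActivity:
    def _summary(self, fractions):
        from synaptoscope.caimg import CellActivitySummary

        fractions = np.asarray(fractions, float)
        frames = np.full(3, 100)
        counts = (fractions * 100).astype(int)
        return CellActivitySummary(
            ["control", "drug", "wash"], counts, fractions, frames
        )

    def test_identical_conditions_null_results(self):
        f = np.tile(np.linspace(0.1, 0.5, 6)[:, None], (1, 3))
        rep = compare_activity(self._summary(f))
        assert rep["ks"]["control_vs_drug"].statistic == 0.0
        assert rep["friedman"].statistic == 0.0

    def test_disjoint_distributions_give_ks_one(self):
        f = np.column_stack(
            [np.linspace(0.0, 0.1, 6), np.linspace(0.5, 0.6, 6), np.linspace(0.0, 0.1, 6)]
        )
        rep = compare_activity(self._summary(f))
        assert rep["ks"]["control_vs_drug"].statistic == 1.0

    def test_friedman_matches_rank_formula(self):
        f = np.array(
            [[0.1, 0.3, 0.2], [0.2, 0.5, 0.4], [0.0, 0.2, 0.1],
             [0.3, 0.6, 0.5], [0.1, 0.4, 0.2]]
        )
        rep = compare_activity(self._summary(f))
        assert rep["friedman"].statistic == pytest.approx(
            friedman_stat_brute(f), abs=1e-9
        )

    def test_missing_condition_rejected(self):
        from synaptoscope.caimg import CellActivitySummary

        s = CellActivitySummary(
            ["control", "drug"], np.zeros((6, 2), int), np.zeros((6, 2)), np.full(2, 10)
        )
        with pytest.raises(ValueError):
            compare_activity(s)


class TestEndToEnd:
    def test_movie_to_raster_recovers_most_truth_events(self):
        proto = control_only_protocol(240.0)
        params = CalciumSimParams(n_cells=6, bg_event_rate=0.08, ensemble_rate=0.0,
                                  noise_sd=0.02, pixel_noise_sd=1.0,
                                  field_size=(160.0, 160.0),
                                  cell_diameter_range=(10.0, 16.0), seed=11)
        traces, truth = simulate_calcium_traces(params, proto)
        movie, cells = render_movie(traces, params)
        rois = extract_rois(movie)
        assert len(rois) == 6
        dff = compute_dff(roi_traces(movie, rois))
        raster = binarize(detect_transients(dff))
        # match each truth cell to the nearest ROI
        centers = np.array([r.center for r in rois.rois])
        tp = total = 0
        for cell in cells:
            j = int(np.argmin(np.hypot(*(centers - np.array(cell.center)).T)))
            det = np.flatnonzero(raster.matrix[j])
            frames = truth.cell_event_frames[cell.index]
            a, b, _ = match_events(frames, det, 1)
            tp, total = tp + a, total + a + b
        assert total > 20
        assert tp / total >= 0.9
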