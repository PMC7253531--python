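"""ROI detection, trace extraction, smoothing, drift correction, ΔF/F0."""

import numpy as np
import pytest

from capheno import synthetic_data as sd
from capheno import trace_processing as tp
from capheno.errors import BoundsError, DegenerateBaselineError, ParameterError
from capheno.spike_inference import SpikeTrain

from conftest import make_raw


def brute_force_maxima(img, threshold, min_sep, half):
    """Independent O(n²) ROI oracle: strict-threshold local maxima, greedy."""
    h, w = img.shape
    cands = []
    for y in range(half, h - half):
        for x in range(half, w - half):
            v = img[y, x]
            if v <= threshold:
                continue
            neigh = img[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
            if v >= neigh.max():
                cands.append((-v, y, x))
    cands.sort()
    accepted = []
    for _, y, x in cands:
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_sep**2 for ay, ax in accepted):
            accepted.append((y, x))
    return accepted


class TestDetectROIs:
    def test_zero_image_empty(self):
        rois = tp.detect_rois(np.zeros((50, 50)), size_px=7)
        assert len(rois) == 0

    def test_gaussian_blobs_found_within_one_px(self):
        rng = np.random.default_rng(0)
        img = np.zeros((100, 100))
        truth = [(25, 25), (25, 70), (70, 45)]
        yy, xx = np.mgrid[0:100, 0:100]
        for y, x in truth:
            img += 50 * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 2.5**2))
        img += rng.uniform(0, 0.5, img.shape)
        rois = tp.detect_rois(img, size_px=7, intensity_threshold=10, min_separation_px=20)
        assert len(rois) == 3
        for ty, tx in truth:
            d = min(abs(y - ty) + abs(x - tx) for y, x in rois.centers)
            assert d <= 2  # within 1 px per axis

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (40, 40))
        rois = tp.detect_rois(img, size_px=5, intensity_threshold=0.8, min_separation_px=6)
        oracle = brute_force_maxima(img, 0.8, 6, half=2)
        assert rois.centers == oracle

    def test_roi_covers_49_pixels(self):
        rois = tp.ROISet(centers=[(10, 10)], size_px=7)
        assert rois.size_px**2 == 49
        assert rois.half == 3


class TestExtractTraces:
    def _movie(self, frames):
        m = tp.MovieStack(frames=np.asarray(frames, float))
        m.geometry = sd.AcquisitionGeometry(fps=20, frame_shape=frames.shape[1:], duration=frames.shape[0] / 20)
        return m

    def test_constant_movie(self):
        frames = np.full((10, 20, 20), 7.5)
        movie = self._movie(frames)
        trace = tp.extract_traces(movie, tp.ROISet(centers=[(10, 10)], size_px=7))[0]
        assert np.allclose(trace.values, 7.5)

    def test_mean_of_0_to_48(self):
        frames = np.zeros((5, 20, 20))
        frames[:, 7:14, 7:14] = np.arange(49, dtype=float).reshape(7, 7)
        movie = self._movie(frames)
        trace = tp.extract_traces(movie, tp.ROISet(centers=[(10, 10)], size_px=7))[0]
        assert np.allclose(trace.values, 24.0)

    def test_single_pixel_roi_identity(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 1, (30, 10, 10))
        movie = self._movie(frames)
        trace = tp.extract_traces(movie, tp.ROISet(centers=[(4, 6)], size_px=1))[0]
        assert np.array_equal(trace.values, frames[:, 4, 6])

    def test_out_of_frame_roi_raises(self):
        movie = self._movie(np.zeros((5, 10, 10)))
        with pytest.raises(BoundsError):
            tp.extract_traces(movie, tp.ROISet(centers=[(1, 5)], size_px=7))


class TestSmooth:
    def test_constant_unchanged(self):
        trace = make_raw(np.full(100, 3.0))
        assert np.allclose(tp.smooth(trace, 5).values, 3.0)

    def test_unit_impulse(self):
        v = np.zeros(50)
        v[25] = 1.0
        out = tp.smooth(make_raw(v), 5).values
        assert np.allclose(out[23:28], 0.2)
        assert np.allclose(out[:23], 0.0) and np.allclose(out[28:], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            tp.smooth(make_raw(np.zeros(10)), 4)

    def test_oversized_window_rejected(self):
        with pytest.raises(ParameterError):
            tp.smooth(make_raw(np.zeros(10)), 11)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=200), rng.normal(size=200)
        sum_then = tp.smooth(make_raw(a + b), 5).values
        then_sum = tp.smooth(make_raw(a), 5).values + tp.smooth(make_raw(b), 5).values
        assert np.allclose(sum_then, then_sum)

    def test_length_preserved(self):
        out = tp.smooth(make_raw(np.arange(33, dtype=float)), 5)
        assert out.n_frames == 33


class TestCorrectDrift:
    def test_constant_unchanged(self):
        trace = make_raw(np.full(1200, 50.0))  # 60 s at 20 FPS
        out = tp.correct_drift(trace, block_s=25.0)
        assert np.allclose(out.values, 50.0, rtol=1e-9)

    def test_small_ramp_restored_to_baseline(self):
        # 1.5% photobleaching-scale ramp on baseline 100 over 300 s
        n = 6000
        t = np.arange(n) / 20.0
        ramp = 1.5 * t / t[-1]
        out = tp.correct_drift(make_raw(100.0 + ramp), block_s=25.0).values
        interior = slice(500, n - 500)  # exclude first/last block
        assert np.all(np.abs(out[interior] - 100.0) < 1.0)

    def test_mean_preserved(self):
        rng = np.random.default_rng(2)
        n = 4000
        t = np.arange(n) / 20.0
        v = 100 + 3 * np.sin(2 * np.pi * t / 120) + 0.01 * t + rng.normal(0, 0.5, n)
        out = tp.correct_drift(make_raw(v), block_s=25.0)
        assert abs(out.values.mean() - v.mean()) / v.mean() < 0.005

    def test_transient_amplitudes_preserved(self, model):
        # tau = 1 s transients riding a 0.01 Hz sinusoidal drift
        geom = sd.AcquisitionGeometry(duration=300.0)
        times = np.arange(20.0, 280.0, 15.0)
        train = SpikeTrain(times=times, duration=geom.duration)
        drift = lambda t: 2.0 * np.sin(2 * np.pi * 0.01 * np.asarray(t))
        clean = sd.render_fluorescence(train, model, geom, baseline=100.0)
        drifted = sd.render_fluorescence(train, model, geom, baseline=100.0, drift=drift)
        corrected = tp.correct_drift(make_raw(drifted.values), block_s=25.0).values
        onsets = (times * geom.fps).astype(int)

        def amplitudes(v):
            # peak minus local pre-onset level (the 5 frames before onset)
            return np.array([v[o] - v[o - 5 : o].mean() for o in onsets])

        amp_clean = amplitudes(clean.values)
        amp_corr = amplitudes(corrected)
        assert np.all(np.abs(amp_corr - amp_clean) / amp_clean < 0.05)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(100, 1, 2000), rng.normal(0, 1, 2000)
        sum_then = tp.correct_drift(make_raw(a + b), 25.0).values
        then_sum = (
            tp.correct_drift(make_raw(a), 25.0).values
            + tp.correct_drift(make_raw(b), 25.0).values
        )
        assert np.allclose(sum_then, then_sum)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ParameterError):
            tp.correct_drift(make_raw(np.zeros(100) + 1.0), block_s=25.0)


class TestBaselineAndNormalization:
    def test_f0_of_constant(self):
        assert tp.estimate_f0(make_raw(np.full(100, 42.0))) == pytest.approx(42.0)

    def test_f0_robust_to_sparse_transients(self):
        v = np.full(1000, 100.0)
        v[::20] = 130.0  # transients occupy 5% of frames
        assert abs(tp.estimate_f0(make_raw(v)) - 100.0) / 100.0 < 0.01

    def test_zero_trace_degenerate(self):
        with pytest.raises(DegenerateBaselineError):
            tp.estimate_f0(make_raw(np.zeros(100)))

    def test_dff_zero_when_at_baseline(self):
        out = tp.normalize_dff(make_raw(np.full(10, 80.0)), f0=80.0)
        assert np.allclose(out.values, 0.0)

    def test_dff_one_percent(self):
        out = tp.normalize_dff(make_raw(np.full(10, 101.0)), f0=100.0)
        assert np.allclose(out.values, 1.0)

    def test_roundtrip_inversion(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(90, 150, 100)
        f0 = 100.0
        dff = tp.normalize_dff(make_raw(v), f0)
        back = f0 * (1 + dff.values / 100.0)
        assert np.allclose(back, v)

    def test_dff_monotone_in_fstar(self):
        f0 = 50.0
        lo = tp.normalize_dff(make_raw(np.array([60.0])), f0).values[0]
        hi = tp.normalize_dff(make_raw(np.array([61.0])), f0).values[0]
        assert hi > lo

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ParameterError):
            tp.normalize_dff(make_raw(np.ones(5)), f0=0.0)


class TestFovExtent:
    @pytest.mark.parametrize(
        "n_px,expected_mm", [(960, 4.224), (720, 3.168), (0, 0.0)]
    )
    def test_camera_geometry(self, n_px, expected_mm):
        assert tp.fov_extent(n_px, 4.40) == pytest.approx(expected_mm)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            tp.fov_extent(-1, 4.4)


class TestCsvRoundtrip:
    def test_traces_roundtrip(self, tmp_path):
        traces = [make_raw(np.arange(40, dtype=float) + i) for i in range(3)]
        path = tmp_path / "traces.csv"
        tp.write_traces_csv(path, traces, ids=["a", "b", "c"])
        back, ids = tp.read_traces_csv(path)
        assert ids == ["a", "b", "c"]
        for orig, rt in zip(traces, back):
            assert np.allclose(orig.values, rt.values)
            assert rt.fps == pytest.approx(20.0)

    def test_rois_roundtrip(self, tmp_path):
        rois = tp.ROISet(centers=[(3, 4), (10, 12)], size_px=7)
        path = tmp_path / "rois.csv"
        tp.write_rois_csv(path, rois)
        back = tp.read_rois_csv(path)
        assert back.centers == rois.centers and back.size_px == 7
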