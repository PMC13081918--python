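import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organoflow import (
    CalibrationCurve,
    ImageStack,
    fit_calibration,
    gradient_offsets,
    intensity_to_concentration,
    roi_mean_timeseries,
)
from organoflow.errors import AlignmentError, CalibrationError, GeometryError, InversionError
from organoflow.rois import Disc, ROISet


def make_stack(frames, pixel_size=10.0):
    frames = np.asarray(frames, dtype=float)
    return ImageStack(frames=frames, timestamps=np.arange(len(frames), dtype=float) + 1,
                      pixel_size=pixel_size)


class TestFitCalibration:
    def test_exact_affine_data(self):
        curve = fit_calibration([0.0, 25.0, 50.0], [10.0, 60.0, 110.0])
        assert curve.slope == pytest.approx(2.0, rel=1e-12)
        assert curve.intercept == pytest.approx(10.0, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.conc_range == (0.0, 50.0)

    def test_constant_intensities_give_zero_slope_and_r2(self):
        curve = fit_calibration([0.0, 25.0, 50.0], [42.0, 42.0, 42.0])
        assert curve.slope == 0.0
        assert curve.r_squared == 0.0

    def test_too_few_distinct_levels_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([0.0, 50.0], [1.0, 2.0])
        with pytest.raises(CalibrationError):
            fit_calibration([10.0, 10.0, 10.0], [1.0, 2.0, 3.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([0.0, 25.0, 50.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(1e-3, 1e3), shift=st.floats(-1e3, 1e3))
    def test_r_squared_invariant_under_affine_intensity_rescaling(self, scale, shift):
        levels = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        rng = np.random.default_rng(7)
        intens = 3.0 * levels + 5.0 + rng.normal(0, 2.0, levels.size)
        r2a = fit_calibration(levels, intens).r_squared
        r2b = fit_calibration(levels, scale * intens + shift).r_squared
        assert r2b == pytest.approx(r2a, abs=1e-9)

    def test_curve_save_load_roundtrip(self, tmp_path):
        curve = fit_calibration([0.0, 25.0, 50.0], [10.0, 61.0, 110.0])
        curve.save(tmp_path / "cal.txt")
        loaded = CalibrationCurve.load(tmp_path / "cal.txt")
        assert loaded == curve


class TestInversion:
    def test_intensity_at_intercept_maps_to_zero(self):
        stack = make_stack(np.full((2, 4, 4), 10.0))
        curve = CalibrationCurve(2.0, 10.0, 1.0, (0.0, 50.0))
        conc = intensity_to_concentration(stack, curve)
        assert not conc.frames.any()
        assert conc.clamped_fraction == 0.0

    def test_below_intercept_clamped_and_counted(self):
        frames = np.full((1, 4, 4), 10.0)
        frames[0, 0, 0] = 4.0  # below the intercept
        conc = intensity_to_concentration(make_stack(frames),
                                          CalibrationCurve(2.0, 10.0, 1.0, (0.0, 50.0)))
        assert conc.frames.min() == 0.0
        assert conc.clamped_fraction == pytest.approx(1 / 16)

    def test_zero_slope_rejected(self):
        with pytest.raises(InversionError):
            intensity_to_concentration(make_stack(np.ones((1, 4, 4))),
                                       CalibrationCurve(0.0, 1.0, 0.0, (0.0, 50.0)))

    def test_affine_roundtrip_recovers_concentration(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(0, 50, (3, 8, 8))
        stack = make_stack(2.0 * truth + 10.0)
        conc = intensity_to_concentration(stack, CalibrationCurve(2.0, 10.0, 1.0, (0, 50)))
        assert np.allclose(conc.frames, truth, rtol=1e-12, atol=1e-12)


class TestRoiMeans:
    def test_uniform_frame_value(self):
        stack = make_stack(np.full((3, 20, 20), 5.5))
        times, series = roi_mean_timeseries(stack, ROISet({"r": Disc(100.0, 100.0, 40.0)}))
        assert np.allclose(series["r"], 5.5)
        assert list(times) == [1.0, 2.0, 3.0]

    def test_linear_in_x_frame_matches_centroid(self):
        W = H = 50
        px = 2.0
        x = (np.arange(W) + 0.5) * px
        frame = np.broadcast_to(x[None, :], (H, W)).copy()  # intensity = x um
        stack = make_stack(frame[None, :, :], pixel_size=px)
        rois = ROISet({"a": Disc(30.0, 50.0, 10.0), "b": Disc(70.0, 20.0, 10.0)})
        _, series = roi_mean_timeseries(stack, rois)
        assert series["a"][0] == pytest.approx(30.0, abs=px)
        assert series["b"][0] == pytest.approx(70.0, abs=px)

    def test_stacked_rois_on_vertical_gradient_are_ordered(self):
        H = W = 60
        frame = np.linspace(10, 0, H)[:, None] * np.ones((1, W))  # bright at top row
        stack = make_stack(frame[None], pixel_size=1.0)
        rois = ROISet({"top": Disc(30.0, 10.0, 8.0),
                       "mid": Disc(30.0, 30.0, 8.0),
                       "bot": Disc(30.0, 50.0, 8.0)})
        _, s = roi_mean_timeseries(stack, rois)
        assert s["top"][0] > s["mid"][0] > s["bot"][0]

    def test_roi_outside_frame_rejected(self):
        stack = make_stack(np.zeros((1, 10, 10)), pixel_size=1.0)
        with pytest.raises(GeometryError):
            roi_mean_timeseries(stack, ROISet({"r": Disc(20.0, 5.0, 3.0)}))


class TestGradientOffsets:
    def test_identical_series_zero_offset_and_stability(self):
        t = np.arange(10.0)
        s = {"a": np.sin(t), "b": np.sin(t)}
        rep = gradient_offsets(t, s, window=5.0)
        assert np.allclose(rep.offsets[("a", "b")], 0.0)
        assert rep.stability[("a", "b")] == 0.0

    def test_constant_shift_gives_constant_offset(self):
        t = np.arange(20.0)
        base = np.cos(t / 3)
        rep = gradient_offsets(t, {"a": base + 4.0, "b": base}, window=10.0)
        assert np.allclose(rep.offsets[("a", "b")], 4.0)
        assert rep.stability[("a", "b")] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_via_accessor(self):
        t = np.arange(10.0)
        rng = np.random.default_rng(0)
        s = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        rep = gradient_offsets(t, s, window=5.0)
        assert np.allclose(rep.offset("b", "a"), -rep.offset("a", "b"))

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(-100, 100))
    def test_translation_invariance(self, shift):
        t = np.arange(12.0)
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        r1 = gradient_offsets(t, {"a": a, "b": b}, window=6.0)
        r2 = gradient_offsets(t, {"a": a + shift, "b": b + shift}, window=6.0)
        assert np.allclose(r1.offsets[("a", "b")], r2.offsets[("a", "b")], atol=1e-9)

    def test_mismatched_series_length_rejected(self):
        with pytest.raises(AlignmentError):
            gradient_offsets(np.arange(5.0),
                             {"a": np.zeros(5), "b": np.zeros(4)}, window=2.0)

    def test_window_longer_than_span_rejected(self):
        with pytest.raises(ValueError):
            gradient_offsets(np.arange(5.0),
                             {"a": np.zeros(5), "b": np.zeros(5)}, window=10.0)
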