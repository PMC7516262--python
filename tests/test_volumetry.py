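"""Pixel-area law, smoothing, swept-volume integration, curve rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tofspiro import (
    DepthFrame,
    DepthSequence,
    SensorGeometry,
    anterior_fvc,
    pixel_area,
    scale_curve,
    smooth_frame,
    volume_curve,
)
from tofspiro.volumetry import VolumeCurve

from conftest import flat_sequence

GEOM = SensorGeometry()


class TestPixelArea:
    def test_hand_computed_values(self):
        # (700 tan31°/224) x (700 tan22.5°/171)
        expected_350 = (
            700 * math.tan(math.radians(31)) / 224
            * 700 * math.tan(math.radians(22.5)) / 171
        )
        assert pixel_area(350.0) == pytest.approx(expected_350, rel=1e-12)
        assert pixel_area(350.0) == pytest.approx(3.184, abs=5e-4)
        assert pixel_area(1000.0) == pytest.approx(25.99, abs=5e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(d=st.floats(min_value=1.0, max_value=5000.0))
    def test_quadratic_distance_scaling(self, d):
        assert pixel_area(2 * d) == pytest.approx(4 * pixel_area(d), rel=1e-12)

    def test_independent_of_pixel_indices(self):
        assert pixel_area(400.0, 0, 0) == pixel_area(400.0, 223, 170)

    def test_vectorized_over_distance(self):
        d = np.array([100.0, 200.0, 400.0])
        areas = pixel_area(d)
        assert areas.shape == (3,)
        np.testing.assert_allclose(areas[1:] / areas[:-1], 4.0)

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValueError):
            pixel_area(0.0)


class TestSmoothFrame:
    def test_constant_frame_unchanged(self):
        frame = DepthFrame(np.full((30, 30), 350.0), 0.0)
        np.testing.assert_allclose(smooth_frame(frame).depth, 350.0, atol=1e-9)

    def test_spike_attenuated_by_center_weight(self):
        depth = np.full((31, 31), 350.0)
        depth[15, 15] += 20.0
        out = smooth_frame(DepthFrame(depth, 0.0)).depth
        assert out[15, 15] - 350.0 < 20.0 / 7.0
        # the spike's mass is redistributed, not destroyed
        assert (out - 350.0).sum() == pytest.approx(20.0, rel=1e-9)

    def test_invalid_pixels_excluded_and_renormalized(self):
        depth = np.full((20, 20), 300.0)
        validity = np.ones((20, 20), bool)
        depth[10, 10] = 9000.0        # garbage under an invalid flag
        validity[10, 10] = False
        out = smooth_frame(DepthFrame(depth, 0.0, validity))
        assert np.allclose(out.depth[validity], 300.0, atol=1e-9)
        assert not out.validity[10, 10]

    def test_kernel_mass_is_unit(self):
        """A unit impulse spreads to weights summing to one."""
        depth = np.zeros((31, 31)) + 100.0
        depth[15, 15] += 1.0
        out = smooth_frame(DepthFrame(depth, 0.0)).depth - 100.0
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        # support is exactly 7x7
        assert np.all(out[:12, :] < 1e-15)
        assert out[12, 15] > 0


class TestVolumeCurve:
    def test_static_scene_identically_zero(self):
        seq = flat_sequence(350.0, n_frames=40, geometry=GEOM)
        mask = np.zeros(GEOM.shape, bool)
        mask[50:150, 30:130] = True
        curve = volume_curve(seq, mask)
        np.testing.assert_array_equal(curve.volume, 0.0)

    def test_piston_oracle(self):
        """A uniform 10 mm step toward the sensor over a 100x100 ROI sweeps
        area(345 mm) x 10 mm x 10^4 pixels (midpoint-area convention)."""
        dt = GEOM.sampling_interval_s
        frames = [
            DepthFrame(np.full(GEOM.shape, 350.0), 0.0),
            DepthFrame(np.full(GEOM.shape, 340.0), dt),
        ]
        mask = np.zeros(GEOM.shape, bool)
        mask[50:150, 30:130] = True
        curve = volume_curve(DepthSequence(frames, GEOM), mask)
        expected = 1e4 * pixel_area(345.0) * 10.0 / 1000.0
        assert curve.volume[-1] == pytest.approx(expected, rel=5e-3)
        assert expected == pytest.approx(309.4, abs=0.1)

    def test_reversible_displacement_returns_to_zero(self):
        dt = GEOM.sampling_interval_s
        base = np.full(GEOM.shape, 350.0)
        moved = base - 8.0
        frames = [
            DepthFrame(base, 0.0),
            DepthFrame(moved, dt),
            DepthFrame(base.copy(), 2 * dt),
        ]
        mask = np.zeros(GEOM.shape, bool)
        mask[10:100, 10:100] = True
        curve = volume_curve(DepthSequence(frames, GEOM), mask)
        assert abs(curve.volume[-1]) < 1e-9

    def test_motion_away_from_sensor_is_negative(self):
        dt = GEOM.sampling_interval_s
        frames = [
            DepthFrame(np.full(GEOM.shape, 350.0), 0.0),
            DepthFrame(np.full(GEOM.shape, 360.0), dt),
        ]
        mask = np.ones(GEOM.shape, bool)
        curve = volume_curve(DepthSequence(frames, GEOM), mask)
        assert curve.volume[-1] < 0

    def test_skipped_invalid_pixels_counted_and_warned(self):
        dt = GEOM.sampling_interval_s
        validity = np.ones(GEOM.shape, bool)
        validity[:150, :] = False      # most of the ROI invalid
        frames = [
            DepthFrame(np.full(GEOM.shape, 350.0), 0.0, validity),
            DepthFrame(np.full(GEOM.shape, 340.0), dt, validity),
        ]
        mask = np.ones(GEOM.shape, bool)
        with pytest.warns(UserWarning, match="skipped"):
            curve = volume_curve(DepthSequence(frames, GEOM), mask)
        assert curve.skipped_fraction > 0.2

    def test_simulator_recovery_small_scene(self, small_scene):
        """Reduced-resolution end-to-end run recovers the true FVC."""
        from tofspiro import extract_roi
        seq, truth = small_scene
        roi, _ = extract_roi(seq)
        fvc = anterior_fvc(volume_curve(seq, roi))
        assert fvc == pytest.approx(truth.fvc_true, rel=0.02)

    def test_too_few_frames_rejected(self):
        seq = flat_sequence(350.0, n_frames=1, geometry=GEOM)
        with pytest.raises(ValueError, match="2 frames"):
            volume_curve(seq, np.ones(GEOM.shape, bool))


class TestAnteriorFvcAndScaling:
    def _curve(self, volume, fr=45.0):
        volume = np.asarray(volume, dtype=float)
        return VolumeCurve(
            time=np.arange(volume.size) / fr, volume=volume, frame_rate_hz=fr
        )

    def test_peak_to_peak(self):
        curve = self._curve([0, 2500, -500, 0])
        assert anterior_fvc(curve, use_maneuver_window=False) == 3000

    def test_constant_curve_zero(self):
        assert anterior_fvc(self._curve([5.0] * 10), use_maneuver_window=False) == 0

    def test_maneuver_window_excludes_tidal(self, short_waveform):
        """With tidal 500 then forced 3000, the windowed amplitude tracks
        the forced maneuver, not the tidal breaths."""
        wf, truth = short_waveform
        curve = self._curve(truth.volume_true, fr=wf.frame_rate_hz)
        assert anterior_fvc(curve) == pytest.approx(3000, rel=0.01)

    def test_scaling_multiplies_volume_only(self):
        curve = self._curve([0.0, 400.0, 1000.0, 200.0])
        scaled = scale_curve(curve, 3000.0)
        np.testing.assert_allclose(scaled.volume, curve.volume * 3.0)
        np.testing.assert_array_equal(scaled.time, curve.time)
        assert scaled.kind == "eafl_scaled"

    def test_identity_scaling(self):
        """Predicting exactly the anterior amplitude leaves the curve alone."""
        curve = self._curve([0.0, 500.0, 1000.0, 100.0])
        scaled = scale_curve(curve, 1000.0)
        np.testing.assert_allclose(scaled.volume, curve.volume)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            scale_curve(self._curve([0.0, 0.0, 0.0]), 3000.0)
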