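"""Envelope detection, tracking-image formation, CoM localization, display mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import foustrack as ft
from foustrack.synth import Frame
from foustrack.tracking import NoSignalError


def com_oracle(pixels: np.ndarray, roi_size=(100, 100), threshold=0.70):
    """Brute-force re-statement of the localization recipe with explicit loops."""
    best = (-1.0, None)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            if pixels[r, c] > best[0]:
                best = (pixels[r, c], (r, c))
    (r0, c0) = best[1]
    h, w = roi_size
    row0 = max(0, min(pixels.shape[0], max(0, r0 - h // 2) + h) - h)
    col0 = max(0, min(pixels.shape[1], max(0, c0 - w // 2) + w) - w)
    row1, col1 = min(pixels.shape[0], row0 + h), min(pixels.shape[1], col0 + w)
    m = 0.0
    for r in range(row0, row1):
        for c in range(col0, col1):
            m = max(m, pixels[r, c])
    sw = sr = sc = 0.0
    for r in range(row0, row1):
        for c in range(col0, col1):
            v = pixels[r, c]
            if v >= threshold * m:
                sw += v
                sr += v * r
                sc += v * c
    return sr / sw, sc / sw


class TestEnvelope:
    def test_constant_amplitude_sinusoid(self):
        t = np.arange(4096) / 40e6
        x = 0.7 * np.sin(2 * np.pi * 5e6 * t)
        env = ft.envelope(x)
        core = env[200:-200]
        np.testing.assert_allclose(core, 0.7, rtol=1e-3)

    def test_zero_input_zero_output(self):
        assert np.all(ft.envelope(np.zeros(256)) == 0.0)

    def test_bounds_signal_from_above(self, rng):
        x = rng.normal(size=1024)
        env = ft.envelope(x)
        assert np.all(env >= np.abs(x) - 1e-9)

    def test_gaussian_tone_peak_matches_quadrature_oracle(self):
        fs, f0 = 40e6, 4e6  # integer samples per carrier period for the boxcar oracle
        t = np.arange(2048) / fs
        t0, sig = 25e-6, 1e-6
        x = np.exp(-0.5 * ((t - t0) / sig) ** 2) * np.cos(2 * np.pi * f0 * (t - t0))
        env = ft.envelope(x)
        # brute-force quadrature demodulation: mix down, boxcar over one period
        period = int(round(fs / f0))
        i = x * np.cos(2 * np.pi * f0 * t)
        q = x * np.sin(2 * np.pi * f0 * t)
        box = np.ones(period) / period
        oracle = 2.0 * np.hypot(np.convolve(i, box, "same"), np.convolve(q, box, "same"))
        assert abs(int(np.argmax(env)) - int(np.argmax(oracle))) <= 1
        assert abs(int(np.argmax(env)) - int(round(t0 * fs))) <= 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ft.envelope(np.array([1.0, np.nan]))


class TestBuildTrackingImage:
    def test_single_scanline_single_column(self, water):
        frame = Frame(np.random.default_rng(0).normal(size=(1, 128)), 20e6, 0, np.array([0]))
        img = ft.build_tracking_image(frame, water)
        assert img.pixels.shape == (128, 1)
        assert img.axial_spacing == pytest.approx(water.speed_of_sound / 20e6)

    def test_rows_map_to_one_way_depth(self, water):
        fs = 40e6
        frame = Frame(np.zeros((2, 100)), fs, 0, np.array([0, 100]))
        img = ft.build_tracking_image(frame, water)
        assert 40 * img.axial_spacing == pytest.approx(40 / fs * 1500.0)

    def test_empty_frame_rejected(self, water):
        frame = Frame(np.zeros((1, 8)), 20e6, 0, np.array([0]))
        frame.data = np.zeros((0, 8))
        with pytest.raises(ValueError):
            ft.build_tracking_image(frame, water)


class TestBackgroundSubtract:
    def test_constant_image_becomes_zero(self):
        out = ft.background_subtract(np.full((10, 10), 3.3))
        assert np.all(out == 0.0)

    def test_offset_invariance(self, rng):
        img = rng.uniform(0, 1, (30, 30))
        a = ft.background_subtract(img)
        b = ft.background_subtract(img + 5.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_spike_over_flat_background(self):
        img = np.full((9, 9), 2.0)
        img[4, 4] = 10.0
        out = ft.background_subtract(img)
        assert out[4, 4] == pytest.approx(8.0)
        assert out[0, 0] == 0.0

    def test_reference_frame_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            ft.background_subtract(np.zeros((4, 4)), reference=np.zeros((5, 5)))


class TestLocalizeTip:
    def test_toy_image_weighted_mean(self):
        # survivors at threshold 0.7 are the 10 and the 8; CoM = (2, 44/18)
        img = np.ones((5, 5))
        img[2, 2], img[2, 3], img[1, 2] = 10.0, 8.0, 6.0
        tip = ft.localize_tip(img)
        assert tip.row == pytest.approx(2.0)
        assert tip.col == pytest.approx(44.0 / 18.0)

    def test_single_nonzero_pixel(self):
        img = np.zeros((40, 40))
        img[13, 27] = 5.0
        tip = ft.localize_tip(img)
        assert (tip.row, tip.col) == (13.0, 27.0)

    def test_symmetric_plateau_centers(self):
        img = np.zeros((21, 21))
        img[9:12, 9:12] = 2.0
        tip = ft.localize_tip(img)
        assert (tip.row, tip.col) == (10.0, 10.0)

    def test_all_zero_image_raises_no_signal(self):
        with pytest.raises(NoSignalError):
            ft.localize_tip(np.zeros((10, 10)))

    def test_com_stays_inside_roi_bounds(self, rng):
        img = rng.uniform(0, 1, (50, 60))
        tip = ft.localize_tip(img, ft.TrackerConfig(roi_size=(8, 8)))
        r0, r1, c0, c1 = tip.roi_bounds
        assert r0 <= tip.row <= r1 - 1 and c0 <= tip.col <= c1 - 1

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_weighted_mean(self, seed):
        img = np.random.default_rng(seed).uniform(0.0, 1.0, (20, 20))
        tip = ft.localize_tip(img)
        row, col = com_oracle(img)
        # agreement to floating-point round-off (summation order differs)
        assert tip.row == pytest.approx(row, abs=1e-10)
        assert tip.col == pytest.approx(col, abs=1e-10)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), k=st.floats(1e-3, 1e3))
    def test_intensity_scale_invariance(self, seed, k):
        img = np.random.default_rng(seed).uniform(0.0, 1.0, (25, 25))
        a = ft.localize_tip(img)
        b = ft.localize_tip(k * img)
        assert a.row == pytest.approx(b.row, rel=1e-12)
        assert a.col == pytest.approx(b.col, rel=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           th=st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)))
    def test_raising_threshold_never_adds_survivors(self, seed, th):
        img = np.random.default_rng(seed).uniform(0.0, 1.0, (20, 20))
        lo, hi = sorted(th)

        def survivors(frac):
            tip = ft.localize_tip(img, ft.TrackerConfig(threshold_fraction=frac))
            r0, r1, c0, c1 = tip.roi_bounds
            roi = img[r0:r1, c0:c1]
            return int((roi >= frac * roi.max()).sum())

        assert survivors(hi) <= survivors(lo)


class TestMapToDisplay:
    def test_boresight_column_maps_to_vertical(self, sector_probe, water):
        spacing = water.speed_of_sound / 40e6
        x, z = ft.map_to_display((1000.0, 45.0), sector_probe, spacing)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert z == pytest.approx(1000.0 * spacing)

    def test_45_degree_beam_at_5cm(self, sector_probe):
        spacing = 1500.0 / 40e6
        row = 0.05 / spacing
        x, z = ft.map_to_display((row, 90.0), sector_probe, spacing)  # +45 degree beam
        assert x == pytest.approx(0.05 / math.sqrt(2), rel=1e-9)  # 3.54 cm
        assert z == pytest.approx(0.05 / math.sqrt(2), rel=1e-9)

    def test_linear_probe_returns_beam_offset_and_depth(self, linear_probe):
        spacing = 1500.0 / 40e6
        x, z = ft.map_to_display((100.0, 0.0), linear_probe, spacing)
        assert x == pytest.approx(-linear_probe.aperture_width / 2)
        assert z == pytest.approx(100.0 * spacing)

    def test_column_outside_beam_table_rejected(self, sector_probe):
        with pytest.raises(ValueError, match="beam table"):
            ft.map_to_display((10.0, 95.0), sector_probe, 1e-5)


@pytest.fixture(scope="module")
def small_sector():
    return ft.make_probe("phased_sector", 16, 0.125e-3, 6e6, fov_angle=90.0,
                         focus_depth=0.055, n_scanlines=31)


class TestTrackSequence:
    def test_straight_catheter_display_closure(self, water):
        # simulate the sensor at the display coordinates reported for the
        # straight catheter and check the overlay marker lands back there
        probe = ft.make_probe("phased_sector", 16, 0.125e-3, 6e6, fov_angle=90.0,
                              focus_depth=0.055)
        pose = ft.SensorPose((0.0326, 0.0544))
        rec = ft.generate_frame(probe, pose, max_depth=0.075)
        (tip,) = ft.track_sequence(rec)
        r = math.hypot(*pose.position)
        tol = water.speed_of_sound / 40e6 + r * math.radians(1.0)  # axial pixel + beam spacing
        assert math.hypot(tip.x - 0.0326, tip.z - 0.0544) < tol

    def test_single_frame_equals_localize_tip(self, small_sector, water):
        rec = ft.generate_frame(small_sector, ft.SensorPose((0.0, 0.05)),
                                max_depth=0.06, sample_rate=20e6)
        (tip,) = ft.track_sequence(rec)
        img = ft.build_tracking_image(rec.frames[0], water, small_sector, frame_index=0)
        direct = ft.localize_tip(ft.background_subtract(img))
        assert tip.row == direct.row and tip.col == direct.col

    def test_high_snr_sequence_is_subpixel_stable(self, small_sector):
        rec = ft.generate_sequence(
            12, small_sector, ft.SensorPose((0.005, 0.05)),
            noise=ft.NoiseSpec(1e-3), seed=21, max_depth=0.06, sample_rate=20e6,
        )
        peak = max(ft.envelope(f.data, axis=1).max() for f in rec.frames)
        assert peak > 100 * 1e-3  # confirm high-SNR regime
        tips = ft.track_sequence(rec)
        rows = [t.row for t in tips]
        cols = [t.col for t in tips]
        assert all(t.flag is None for t in tips)
        assert np.std(rows) < 1.0 and np.std(cols) < 1.0

    def test_all_noise_frames_are_flagged(self, small_sector):
        rec = ft.generate_sequence(
            5, small_sector, ft.SensorPose((0.0, 0.05)),
            pulse=ft.PulseSpec(6e6, amplitude=0.0), noise=ft.NoiseSpec(1.0),
            seed=8, max_depth=0.06, sample_rate=20e6,
        )
        tips = ft.track_sequence(rec)
        assert [t.flag for t in tips] == ["no_signal"] * 5
        assert all(math.isnan(t.row) for t in tips)

    def test_empty_record_rejected(self, small_sector, water):
        rec = ft.FOUSRecord([], small_sector, water, ft.SensorPose((0, 0.05)))
        with pytest.raises(ValueError):
            ft.track_sequence(rec)
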