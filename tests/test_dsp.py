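import numpy as np
import pytest

from ovitrack import (ArenaConfig, RadarConfig, ClutterNormalizer, Detection,
                      assemble_track, detect_target, estimate_clutter,
                      frame_to_map, free_space_gain, normalize_frame,
                      range_resolution)
from ovitrack.simulate import (ClutterScene, polar_from_arena,
                               synthesize_beat_signal, synthesize_map)

C = 299_792_458.0


class TestClosedForms:
    def test_range_resolution_values(self):
        assert range_resolution(3e9) == pytest.approx(0.05, abs=5e-4)
        assert range_resolution(800e6) == pytest.approx(0.1874, abs=5e-5)
        assert range_resolution(1e9) == C / 2e9  # machine-precision identity

    def test_range_resolution_monotone_in_bandwidth(self):
        bw = np.geomspace(1e8, 1e11, 20)
        res = [range_resolution(b) for b in bw]
        assert np.all(np.diff(res) < 0)

    def test_range_resolution_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            range_resolution(0.0)

    def test_free_space_gain_values(self):
        assert free_space_gain(77e9, 24e9) == pytest.approx(10.13, abs=0.005)
        assert free_space_gain(5e9, 5e9) == 0.0
        assert free_space_gain(48e9, 24e9) == pytest.approx(
            20 * np.log10(2), abs=1e-12)

    def test_free_space_gain_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            free_space_gain(-1.0, 24e9)


class TestFrameToMap:
    def test_single_target_argmax_within_one_bin(self, quiet_radar, arena):
        r_true, th_true = 4.3, 8.0
        raw = synthesize_beat_signal((r_true, th_true), ClutterScene.empty(),
                                     quiet_radar)
        m = frame_to_map(raw, quiet_radar)
        i, j = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert abs(i * quiet_radar.range_bin_width - r_true) <= \
            quiet_radar.range_bin_width
        sin_bin = (j - quiet_radar.n_angle_bins // 2) / (
            quiet_radar.n_angle_bins * quiet_radar.element_spacing)
        bin_err = abs(sin_bin - np.sin(np.radians(th_true))) * \
            quiet_radar.n_angle_bins * quiet_radar.element_spacing
        assert bin_err <= 1.0

    def test_zero_input_gives_zero_map(self, quiet_radar):
        raw = np.zeros((quiet_radar.n_fast_samples, quiet_radar.n_channels),
                       complex)
        assert np.all(frame_to_map(raw, quiet_radar).values == 0)

    def test_two_separated_targets_give_two_peaks(self, quiet_radar):
        scene = ClutterScene([[2.0, -15.0, 1.0]])
        raw = synthesize_beat_signal((6.0, 15.0), scene, quiet_radar)
        m = frame_to_map(raw, quiet_radar).values
        # brute-force strict local maxima above a tenth of the global max
        peaks = []
        for i in range(1, m.shape[0] - 1):
            for j in range(1, m.shape[1] - 1):
                if m[i, j] >= 0.1 * m.max() and \
                        m[i, j] == m[i - 1:i + 2, j - 1:j + 2].max():
                    peaks.append((i, j))
        assert len(peaks) == 2
        ranges = sorted(p[0] * quiet_radar.range_bin_width for p in peaks)
        assert ranges[0] == pytest.approx(2.0, abs=0.05)
        assert ranges[1] == pytest.approx(6.0, abs=0.05)

    def test_shape_mismatch_rejected(self, radar):
        with pytest.raises(ValueError):
            frame_to_map(np.zeros((10, 3), complex), radar)


class TestClutterEstimation:
    def test_identical_frames_give_zero_std(self):
        frame = np.random.default_rng(0).uniform(1, 2, (8, 6))
        stats = estimate_clutter([frame] * 5)
        np.testing.assert_allclose(stats.mean, frame)
        np.testing.assert_allclose(stats.std, 0, atol=1e-12)

    def test_iid_noise_mean_within_four_sigma(self, rng):
        mu, sigma, n = 3.0, 0.5, 1000
        frames = rng.normal(mu, sigma, (n, 10, 8))
        stats = estimate_clutter(frames)
        assert np.all(np.abs(stats.mean - mu) < 4 * sigma / np.sqrt(n))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_clutter(np.ones((1, 4, 4)))


class TestNormalization:
    def test_signal_equal_to_mean_gives_zero(self, rng):
        frames = rng.normal(2.0, 0.3, (50, 6, 5))
        stats = estimate_clutter(frames)
        D = normalize_frame(stats.mean.copy(), stats)
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_background_standardizes_to_unit_scale(self, rng):
        frames = rng.normal(2.0, 0.3, (600, 25, 25))
        stats = estimate_clutter(frames[:300])
        D = normalize_frame(frames[300], stats)
        assert abs(D.mean()) < 0.2
        assert abs(D.std() - 1.0) < 0.2

    def test_ten_sigma_cell_maps_to_ten(self, rng):
        frames = rng.normal(5.0, 0.4, (200, 6, 6))
        stats = estimate_clutter(frames)
        S = stats.mean.copy()
        S[2, 3] = stats.mean[2, 3] + 10 * stats.std[2, 3]
        D = normalize_frame(S, stats)
        assert D[2, 3] == pytest.approx(10.0)

    def test_round_trip_grand_statistics(self, rng):
        # ensemble of standardized background frames: mean ~ 0, sd ~ 1
        frames = rng.normal(1.5, 0.25, (2000, 12, 10))
        norm = ClutterNormalizer().fit(frames[:1000])
        D = norm.transform(frames[1000:])
        assert abs(D.mean()) < 0.05
        assert 0.9 < D.std() < 1.1

    def test_shape_mismatch_rejected(self, rng):
        stats = estimate_clutter(rng.normal(size=(5, 4, 4)))
        with pytest.raises(ValueError):
            normalize_frame(np.zeros((3, 3)), stats)


class TestDetection:
    def test_all_zero_field_is_invalid(self, radar):
        D = np.zeros((radar.n_range_bins, radar.n_angle_bins))
        det = detect_target(D, radar, threshold=5.0)
        assert not det.valid

    def test_injected_peak_detected_at_cell(self, radar):
        D = np.zeros((radar.n_range_bins, radar.n_angle_bins))
        D[40, 20] = 10.0
        det = detect_target(D, radar, threshold=5.0)
        assert det.valid
        assert det.range_m == pytest.approx(40 * radar.range_bin_width)
        sin_th = (20 - radar.n_angle_bins // 2) / (
            radar.n_angle_bins * radar.element_spacing)
        assert det.azimuth_deg == pytest.approx(
            np.degrees(np.arcsin(sin_th)))

    def test_tie_breaks_toward_smaller_range_then_angle(self, radar):
        D = np.zeros((radar.n_range_bins, radar.n_angle_bins))
        D[30, 40] = D[50, 10] = 8.0
        det = detect_target(D, radar, threshold=5.0)
        assert det.range_m == pytest.approx(30 * radar.range_bin_width)
        D2 = np.zeros_like(D)
        D2[30, 10] = D2[30, 40] = 8.0
        det2 = detect_target(D2, radar, threshold=5.0)
        sin_th = (10 - radar.n_angle_bins // 2) / (
            radar.n_angle_bins * radar.element_spacing)
        assert det2.azimuth_deg == pytest.approx(
            np.degrees(np.arcsin(sin_th)))

    def test_probability_non_decreasing_in_amplitude(self, arena):
        radar = RadarConfig(noise_sigma=0.5, n_range_bins=64, n_angle_bins=32)
        rng = np.random.default_rng(11)
        rates = []
        for amp in (0.5, 1.5, 2.5, 3.5, 4.5):
            hits = 0
            for _ in range(200):
                f = synthesize_map((2.0, 0.0), ClutterScene.empty(), radar,
                                   seed=rng, target_amplitude=amp)
                # noise-only field has std sigma/sqrt(2) per component
                D = f.values / (radar.noise_sigma / np.sqrt(2))
                det = detect_target(D, radar, threshold=5.0)
                if det.valid and abs(det.range_m - 2.0) < 0.2:
                    hits += 1
            rates.append(hits / 200)
        assert all(b >= a - 0.03 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestAssembleTrack:
    def _detections(self, arena, radar, points, valid=None):
        dets = []
        for k, (t, x, y) in enumerate(points):
            ok = True if valid is None else valid[k]
            if ok:
                r, th = polar_from_arena(x, y, arena)
                dets.append(Detection(t, r, th, 10.0, True))
            else:
                dets.append(Detection(t, np.nan, np.nan, 0.0, False))
        return dets

    def test_gapless_track_is_pure_coordinate_transform(self, arena, radar):
        pts = [(0.0, 0.2, 1.0), (1.0, 0.1, 2.0), (2.0, -0.3, 3.0)]
        track = assemble_track(self._detections(arena, radar, pts), 1.0,
                               arena)
        np.testing.assert_allclose(track.x, [0.2, 0.1, -0.3], atol=1e-9)
        np.testing.assert_allclose(track.y, [1.0, 2.0, 3.0], atol=1e-9)

    def test_single_gap_fills_at_midpoint(self, arena, radar):
        pts = [(0.0, 0.0, 1.0), (1.0, 0.0, 1.5), (2.0, 0.0, 2.0)]
        dets = self._detections(arena, radar, pts, valid=[True, False, True])
        track = assemble_track(dets, 1.0, arena)
        assert track.y[1] == pytest.approx(1.5, abs=1e-9)
        assert not track.valid[1]

    def test_dropped_frames_recovered_within_one_bin(self, arena, radar):
        # straight constant-speed track, 20% of frames dropped at random
        rng = np.random.default_rng(5)
        t = np.arange(100) / 10.0
        y = 0.5 + 0.3 * t
        pts = list(zip(t, np.zeros_like(t), y))
        valid = rng.random(100) > 0.2
        valid[0] = valid[-1] = True
        track = assemble_track(self._detections(arena, radar, pts, valid),
                               10.0, arena)
        rmse = np.sqrt(np.mean((track.y - y) ** 2 + track.x ** 2))
        assert rmse < radar.range_bin_width

    def test_no_valid_detections_rejected(self, arena):
        dets = [Detection(0.0, np.nan, np.nan, 0.0, False)]
        with pytest.raises(ValueError):
            assemble_track(dets, 1.0, arena)


class TestEndToEndRecovery:
    def test_noiseless_recovery_within_half_bin(self, quiet_radar, arena):
        rng = np.random.default_rng(20)
        n_ok = 0
        for _ in range(20):
            x = rng.uniform(-0.9, 0.9)
            y = rng.uniform(1.0, 6.8)
            r_true, th_true = polar_from_arena(x, y, arena)
            if abs(th_true) > quiet_radar.field_of_view / 2:
                continue
            raw = synthesize_beat_signal((x, y), ClutterScene.empty(),
                                         quiet_radar, arena=arena)
            det = detect_target(frame_to_map(raw, quiet_radar).values,
                                quiet_radar, threshold=0.1)
            assert det.valid
            assert abs(det.range_m - r_true) <= \
                quiet_radar.range_bin_width / 2
            sin_err = abs(np.sin(np.radians(det.azimuth_deg)) -
                          np.sin(np.radians(th_true)))
            bin_w = 1.0 / (quiet_radar.n_angle_bins *
                           quiet_radar.element_spacing)
            assert sin_err <= bin_w / 2
            n_ok += 1
        assert n_ok >= 15  # positions outside the beam are skipped
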