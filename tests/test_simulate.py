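import numpy as np
import pytest
from scipy import stats

from ovitrack import ArenaConfig, RadarConfig
from ovitrack.simulate import (ClutterScene, CovariateSpec, SessionData,
                               clutter_complex_map, generate_cohort,
                               generate_session, piecewise_velocity_track,
                               planted_feature_windows, polar_from_arena,
                               synthesize_beat_signal, synthesize_map,
                               wall_clutter_scene)

C = 299_792_458.0

SHORT = ArenaConfig(phase_durations=(1.0, 3.0, 3.0))


class TestBeatSignal:
    def test_single_reflector_peak_at_beat_frequency(self, quiet_radar):
        r_true = 3.7
        raw = synthesize_beat_signal((r_true, 0.0), ClutterScene.empty(),
                                     quiet_radar)
        # oracle: f_b = 2 B r / (c T); locate the plain-FFT argmax
        f_b = 2 * quiet_radar.bandwidth * r_true / (C * quiet_radar.ramp_time)
        fs = quiet_radar.n_fast_samples / quiet_radar.ramp_time
        expected_bin = round(f_b * quiet_radar.n_fast_samples / fs)
        spec = np.abs(np.fft.fft(raw[:, 0]))[: quiet_radar.n_range_bins]
        assert int(np.argmax(spec)) == expected_bin

    def test_no_reflectors_no_noise_is_zero(self, quiet_radar):
        raw = synthesize_beat_signal(None, ClutterScene.empty(), quiet_radar)
        assert np.all(raw == 0)

    def test_boresight_target_has_equal_channel_phase(self, quiet_radar):
        raw = synthesize_beat_signal((2.0, 0.0), ClutterScene.empty(),
                                     quiet_radar)
        phases = np.angle(raw[10, :])
        assert np.allclose(phases, phases[0])

    def test_target_behind_radar_rejected(self, quiet_radar):
        with pytest.raises(ValueError, match="behind"):
            synthesize_beat_signal((1.0, 120.0), ClutterScene.empty(),
                                   quiet_radar)


class TestMapSynthesis:
    def test_single_target_argmax_at_cell(self, quiet_radar):
        r, th = 4.0, 6.0
        frame = synthesize_map((r, th), ClutterScene.empty(), quiet_radar)
        i, j = np.unravel_index(np.argmax(frame.values), frame.values.shape)
        assert i == round(r / quiet_radar.range_bin_width)
        ia = np.sin(np.radians(th)) * quiet_radar.n_angle_bins * \
            quiet_radar.element_spacing + quiet_radar.n_angle_bins // 2
        assert j == round(ia)

    def test_clutter_static_noise_varies_across_seeds(self, radar, arena):
        scene = wall_clutter_scene(arena, radar, seed=0)
        cmap = clutter_complex_map(scene, radar)
        f1 = synthesize_map(None, scene, radar, seed=1, _clutter_map=cmap)
        f2 = synthesize_map(None, scene, radar, seed=2, _clutter_map=cmap)
        quiet = RadarConfig(noise_sigma=0.0)
        c1 = synthesize_map(None, scene, quiet, _clutter_map=cmap)
        c2 = synthesize_map(None, scene, quiet, _clutter_map=cmap)
        np.testing.assert_array_equal(c1.values, c2.values)  # static clutter
        assert not np.array_equal(f1.values, f2.values)  # noise differs

    def test_zero_amplitude_target_equals_background(self, radar, arena):
        scene = wall_clutter_scene(arena, radar, seed=0)
        bg = synthesize_map(None, scene, radar, seed=5)
        tg = synthesize_map((0.0, 3.0), scene, radar, seed=5, arena=arena,
                            target_amplitude=0.0)
        np.testing.assert_array_equal(bg.values, tg.values)

    def test_signal_and_map_levels_agree_on_argmax(self, arena):
        from ovitrack.dsp import frame_to_map
        quiet = RadarConfig(noise_sigma=0.0)
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(20):
            x, y = rng.uniform(-0.9, 0.9), rng.uniform(0.8, 6.8)
            _, th = polar_from_arena(x, y, arena)
            if abs(th) > quiet.field_of_view / 2:
                continue
            raw = synthesize_beat_signal((x, y), ClutterScene.empty(), quiet,
                                         arena=arena)
            m_sig = frame_to_map(raw, quiet).values
            m_map = synthesize_map((x, y), ClutterScene.empty(), quiet,
                                   arena=arena).values
            assert np.unravel_index(np.argmax(m_sig), m_sig.shape) == \
                np.unravel_index(np.argmax(m_map), m_map.shape)
            n_checked += 1
        assert n_checked >= 15


class TestSession:
    def test_frame_counts_match_protocol(self, arena):
        radar = RadarConfig(n_range_bins=64, n_angle_bins=16)
        s = generate_session(arena=SHORT, radar=radar, seed=0, frames="map",
                             n_background=25)
        n_expected = sum(int(np.ceil(d * radar.frame_rate))
                         for d in SHORT.phase_durations)
        assert s.phase_frames.shape[0] == n_expected == len(s.ground_truth)
        assert s.background_frames.shape[0] == 25

    def test_zero_background_frames_rejected(self):
        with pytest.raises(ValueError):
            generate_session(arena=SHORT, seed=0, frames="map",
                             n_background=0)

    def test_same_seed_bit_identical(self):
        radar = RadarConfig(n_range_bins=64, n_angle_bins=16)
        a = generate_session(arena=SHORT, radar=radar, seed=3, frames="map",
                             n_background=5)
        b = generate_session(arena=SHORT, radar=radar, seed=3, frames="map",
                             n_background=5)
        np.testing.assert_array_equal(a.phase_frames, b.phase_frames)
        np.testing.assert_array_equal(a.background_frames,
                                      b.background_frames)
        np.testing.assert_array_equal(a.ground_truth.x, b.ground_truth.x)
        assert a.covariates == b.covariates

    def test_hdf5_roundtrip(self, tmp_path):
        radar = RadarConfig(n_range_bins=64, n_angle_bins=16)
        s = generate_session(arena=SHORT, radar=radar, seed=1, frames="map",
                             n_background=5)
        path = tmp_path / "session.h5"
        s.to_hdf5(path)
        back = SessionData.from_hdf5(path, arena=SHORT, radar=radar)
        np.testing.assert_array_equal(back.phase_frames, s.phase_frames)
        np.testing.assert_allclose(back.ground_truth.y, s.ground_truth.y)
        assert back.covariates == pytest.approx(s.covariates)

    def test_stationary_model_emits_no_infrared_events(self):
        from ovitrack.trajectory import MovementState
        states = [MovementState("still", 0.0, 0.0, np.inf)] * 4
        s = generate_session(arena=SHORT, seed=2, frames="none",
                             states=states)
        assert len(s.infrared) == 0

    def test_null_effects_leave_movement_independent_of_covariates(self):
        spec = CovariateSpec.null()
        sessions = generate_cohort(n_sheep=50, arena=SHORT,
                                   covariate_spec=spec, seed=4)
        soc = np.array([s.covariates["sociability"] for s in sessions])
        speed = np.array([
            np.hypot(np.diff(s.ground_truth.x),
                     np.diff(s.ground_truth.y)).sum()
            for s in sessions])
        r, p = stats.pearsonr(soc, speed)
        assert abs(r) < 0.3

    def test_phase3_multiplier_suppresses_speed(self):
        arena = ArenaConfig(phase_durations=(1.0, 10.0, 10.0))
        sessions = generate_cohort(n_sheep=50, arena=arena, seed=5)
        diffs = []
        for s in sessions:
            gt = s.ground_truth
            v = np.hypot(np.diff(gt.x), np.diff(gt.y)) * 50.0
            ph = gt.phase[1:]
            diffs.append(v[ph == 2].mean() - v[ph == 3].mean())
        # suppression holds in expectation over the cohort
        t, p = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        assert np.mean(diffs) > 0
        assert p < 0.01

    def test_positive_sociability_coupling_raises_activity(self):
        arena = ArenaConfig(phase_durations=(1.0, 10.0, 10.0))
        sessions = generate_cohort(n_sheep=60, arena=arena, seed=6)
        soc = np.array([s.covariates["sociability"] for s in sessions])
        speed = np.array([
            np.hypot(np.diff(s.ground_truth.x),
                     np.diff(s.ground_truth.y)).sum() for s in sessions])
        r, _ = stats.pearsonr(soc, speed)
        assert r > 0.2


class TestFixtures:
    def test_planted_windows_shapes_and_labels(self):
        df, lab = planted_feature_windows(300, seed=0)
        assert len(df) == 300 and len(lab) == 300
        assert set(lab) <= {0, 1, 2, 3}

    def test_piecewise_track_stays_off_walls(self, arena):
        for seed in range(5):
            traj, edges = piecewise_velocity_track(10, seed=seed)
            assert traj.y.min() > 0 and traj.y.max() < arena.length
            assert len(edges) == 10
            assert np.all((edges > 0) & (edges < 60.0))
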