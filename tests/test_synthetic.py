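"""Simulator: trajectories, rendering, emissions, acoustic channel."""

import numpy as np
import pytest

from batsync.acoustics import Pulse
from batsync.camera import CameraModel
from batsync.synthetic import (AtmosphereModel, CallModel, MicModel, PassTruth,
                               SimConfig, apply_acoustic_channel,
                               render_thermal_frames, sample_pass,
                               sample_search_sequences, simulate_call_emissions,
                               simulate_flight_paths, spawn_rngs)
from batsync.video import detect_blobs, estimate_background, robust_noise_sd


def _paths_config(**kw):
    defaults = dict(night_duration_s=3600.0, pass_rate_per_h=20.0, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestFlightPaths:
    def test_type_counts_follow_flight_mix(self, rng):
        """~784 passes at the observed mix land within 3 sigma of (416, 290, 78)."""
        config = _paths_config(night_duration_s=784 / 20.0 * 3600.0)
        passes = simulate_flight_paths(config, rng)
        n = len(passes)
        counts = {t: sum(p.trajectory_type == t for p in passes)
                  for t in ("straight", "curved", "erratic")}
        for ttype, frac in zip(("straight", "curved", "erratic"), (0.53, 0.37, 0.10)):
            sigma = np.sqrt(n * frac * (1 - frac))
            assert abs(counts[ttype] - n * frac) < 3 * sigma

    def test_degenerate_mix_is_all_straight(self, rng):
        config = _paths_config(flight_mix=(1.0, 0.0, 0.0))
        passes = simulate_flight_paths(config, rng)
        assert passes and all(p.trajectory_type == "straight" for p in passes)

    def test_same_seed_reproduces_waypoints_exactly(self):
        config = _paths_config()
        runs = []
        for _ in range(2):
            passes = simulate_flight_paths(config, np.random.default_rng(config.seed))
            runs.append(np.concatenate([p.waypoints_m.ravel() for p in passes]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_trajectory_shapes(self, camera, rng):
        straight = sample_pass(camera, "straight", 20.0, 7.0, 0.0, rng)
        v = np.diff(straight.waypoints_m, axis=0)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        assert np.allclose(v, v[0], atol=1e-6)

        curved = sample_pass(camera, "curved", 20.0, 7.0, 0.0, rng)
        h = np.diff(curved.waypoints_m[:, :2], axis=0)
        ang = np.degrees(np.arctan2(h[:, 1], h[:, 0]))
        turns = (np.diff(ang) + 180) % 360 - 180
        assert np.all(turns >= -1e-6) or np.all(turns <= 1e-6)  # one sign

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(flight_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SimConfig(p_silent=1.5)
        with pytest.raises(ValueError):
            SimConfig(pass_rate_per_h=float("nan"))


class TestThermalRendering:
    def test_apparent_size_matches_pinhole(self, camera, rng):
        """A bat at 24.8 m subtends ~8.3 px (focal * size / distance)."""
        bp = sample_pass(camera, "straight", 24.8, 5.0, 0.0, rng)
        frames = render_thermal_frames([bp], [], camera, rng, bp.t0, bp.t1, fps=3.0)
        bg = estimate_background(frames.pixels)
        sd = robust_noise_sd(frames.pixels, bg)
        sizes = [b.size_px for f in frames.pixels for b in detect_blobs(f, bg, sd)]
        assert sizes
        expected = camera.focal_px * camera.bat_size_m / 24.8
        assert expected == pytest.approx(8.3, abs=0.1)
        assert np.median(sizes) == pytest.approx(expected, rel=0.2)

    def test_empty_scene_has_no_blobs(self, camera, rng):
        frames = render_thermal_frames([], [], camera, rng, 0.0, 1.0, fps=3.0)
        bg = estimate_background(frames.pixels)
        sd = robust_noise_sd(frames.pixels, bg)
        assert all(not detect_blobs(f, bg, sd) for f in frames.pixels)

    def test_bat_beyond_calibrated_range_invisible(self, camera, rng):
        bp = sample_pass(camera, "straight", 100.0, 7.0, 0.0, rng)
        frames = render_thermal_frames([bp], [], camera, rng, bp.t0, bp.t1, fps=3.0)
        bg = estimate_background(frames.pixels)
        sd = robust_noise_sd(frames.pixels, bg)
        assert all(not detect_blobs(f, bg, sd) for f in frames.pixels)


class TestCallEmissions:
    def test_sample_moments_match_call_model(self, camera):
        rng = np.random.default_rng(7)
        config = _paths_config(night_duration_s=400 * 180.0, pass_rate_per_h=20.0)
        passes = simulate_flight_paths(config, np.random.default_rng(1))
        truth = simulate_call_emissions(passes, CallModel(buzz_probability=0.0,
                                                          social_probability=0.0),
                                        p_silent=0.0, rng=rng)
        onsets = [[e.onset_s for e in pt.emitted] for pt in truth.passes]
        ipis = np.concatenate([np.diff(o) for o in onsets if len(o) > 1]) * 1000.0
        fpeaks = np.array([e.fpeak_khz for pt in truth.passes for e in pt.emitted])
        assert len(fpeaks) >= 584
        assert np.mean(ipis) == pytest.approx(217.0, rel=0.05)
        assert np.mean(fpeaks) == pytest.approx(29.3, rel=0.02)

    def test_fully_silent_night_emits_nothing(self, rng, camera):
        passes = [sample_pass(camera, "straight", 20.0, 7.0, 60.0 * k, rng)
                  for k in range(20)]
        for k, p in enumerate(passes):
            p.pass_id = k
        truth = simulate_call_emissions(passes, CallModel(), p_silent=1.0, rng=rng)
        assert truth.n_emitted == 0
        assert all(pt.silent for pt in truth.passes)

    def test_silent_pass_cannot_carry_pulses(self):
        with pytest.raises(ValueError):
            PassTruth(pass_id=0, trajectory_type="straight", silent=True,
                      emitted=[object()])

    def test_search_sequences_respect_extraction_rules(self):
        rng = np.random.default_rng(3)
        for seq in sample_search_sequences(CallModel(), 50, rng):
            assert len(seq) >= 3
            gaps = np.diff([p.onset_s for p in seq]) * 1000.0
            assert np.all(gaps >= 100.0)
            assert all(p.amplitude_db >= 15.0 for p in seq)


class TestAcousticChannel:
    def _one_pulse_truth(self, camera, rng, distance, heading_to_mic=False):
        bp = sample_pass(camera, "straight", distance, 7.0, 0.0, rng)
        t_mid = (bp.t0 + bp.t1) / 2
        pt = PassTruth(pass_id=0, trajectory_type="straight", silent=False)
        from batsync.synthetic import EmittedPulse, GroundTruthLog
        pt.emitted.append(EmittedPulse(onset_s=t_mid, duration_ms=7.0,
                                       fmin_khz=26.0, fmax_khz=36.0,
                                       fpeak_khz=30.0, source_db=100.0))
        bp.pass_id = 0
        return GroundTruthLog(passes=[pt]), [bp]

    def test_transmission_loss_arithmetic(self):
        atm = AtmosphereModel(alpha_db_per_m=0.3)
        assert atm.transmission_loss(10.0, 30.0) == pytest.approx(23.0)
        assert AtmosphereModel(alpha_db_per_m=0.0).transmission_loss(1.0, 30.0) == 0.0
        # d=0 clamps to 0.1 m rather than diverging
        assert np.isfinite(AtmosphereModel().transmission_loss(0.0, 30.0))

    def test_trigger_threshold_is_strict(self, camera, rng):
        """A pulse arriving 0.1 dB below the 18 dB trigger is not recorded."""
        truth, passes = self._one_pulse_truth(camera, rng, 10.0)
        e = truth.passes[0].emitted[0]
        # calibrate source level so received SNR is exactly 17.9 dB
        mic = MicModel(beam_loss_db=0.0, noise_floor_db=40.0)
        atm = AtmosphereModel(alpha_db_per_m=0.0)
        pos = passes[0].position_at(e.onset_s)
        d = float(np.linalg.norm(mic.position - pos))
        e.source_db = 40.0 + 17.9 + atm.transmission_loss(d, e.fpeak_khz)
        assert apply_acoustic_channel(truth, passes, mic, atm) == []
        assert truth.passes[0].emitted[0].received_snr_db == pytest.approx(17.9)
        e.source_db += 0.2  # 18.1 dB SNR -> recorded
        assert len(apply_acoustic_channel(truth, passes, mic, atm)) == 1

    def test_received_snr_decreases_with_distance(self, camera):
        rng = np.random.default_rng(0)
        snrs = []
        for d in (5.0, 15.0, 30.0, 60.0):
            truth, passes = self._one_pulse_truth(camera, np.random.default_rng(1), d)
            apply_acoustic_channel(truth, passes, MicModel(beam_loss_db=0.0),
                                   AtmosphereModel())
            snrs.append(truth.passes[0].emitted[0].received_snr_db)
        assert all(a > b for a, b in zip(snrs, snrs[1:]))

    def test_every_recorded_pulse_traces_to_one_emission(self, camera):
        rng = np.random.default_rng(5)
        config = _paths_config(night_duration_s=7200.0)
        passes = simulate_flight_paths(config, rng)
        truth = simulate_call_emissions(passes, CallModel(), 0.3, rng)
        recorded = apply_acoustic_channel(truth, passes, MicModel(), AtmosphereModel())
        flags = [e.recorded for pt in truth.passes for e in pt.emitted]
        assert len(recorded) == sum(flags)
        assert truth.n_recorded <= truth.n_emitted
        for pt in truth.passes:
            for e in pt.emitted:
                assert (not e.recorded) or e.received_snr_db >= MicModel().trigger_snr_db


def test_child_streams_are_independent_and_reproducible():
    a1, b1 = spawn_rngs(123, 2)
    a2, b2 = spawn_rngs(123, 2)
    assert a1.random() == a2.random()
    assert b1.random() == b2.random()
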