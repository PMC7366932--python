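"""Synthetic session generator: determinism, calibration, ground truth."""

import numpy as np
import pytest

from swdscope.detection import DetectorConfig, bandpass, count_cycles, detect_swds, envelope
from swdscope.preprocess import build_sweep_set
from swdscope.spectral import _welch_default
from swdscope.staging import MOVEMENT, SLEEP, correct_jumps, correct_sharp_turns
from swdscope.synthetic import (
    SessionConfig,
    simulate_ground_truth,
    simulate_session,
    synth_background,
    synth_swd_waveform,
    synth_trajectory,
    _spindle_train,
)

FS = 2000.0


class TestConfig:
    def test_schedule_duration_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(duration_s=100.0, state_schedule=[("movement", 60.0)])

    def test_fundamental_outside_band_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(swd_fundamental_hz=5.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(swd_rate_per_state={"sleep": -1.0})


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self):
        cfg = SessionConfig(duration_s=120.0, seed=1)
        eeg1, traj1, gt1 = simulate_session(cfg)
        eeg2, traj2, gt2 = simulate_session(SessionConfig(duration_s=120.0, seed=1))
        assert np.array_equal(eeg1.data, eeg2.data)
        assert np.array_equal(traj1.points(), traj2.points())
        assert gt1.events.equals(gt2.events)
        assert np.array_equal(gt1.frame_states, gt2.frame_states)

    def test_lengths_match_config(self):
        cfg = SessionConfig(duration_s=600.0, seed=2)
        eeg, traj, _ = simulate_session(cfg)
        assert eeg.n_samples == int(600.0 * cfg.eeg_fs)
        assert eeg.data.shape[0] == 2
        assert len(traj) == int(600.0 * cfg.video_fps)

    def test_full_session_frame_and_sweep_counts(self):
        # a 3-h session at 2 kHz corresponds to 21.6M samples; checked on
        # the EEG-free layer to keep the suite fast
        cfg = SessionConfig(duration_s=10800.0, seed=3)
        gt, _ = simulate_ground_truth(cfg)
        assert gt.frame_states.size == 216000
        assert gt.sweep_states.size == 1080
        assert int(cfg.duration_s * cfg.eeg_fs) == 21_600_000


class TestWaveform:
    @pytest.mark.parametrize("n_cycles,dur", [(9, 1.0), (3, 1 / 3)])
    def test_duration_is_cycles_over_fundamental(self, n_cycles, dur):
        w = synth_swd_waveform(9.0, n_cycles, 0.3, FS)
        assert w.size == pytest.approx(dur * FS, abs=1)

    def test_peak_amplitude(self):
        w = synth_swd_waveform(9.0, 6, 0.42, FS)
        assert w.max() == pytest.approx(0.42)

    def test_spectral_peak_at_fundamental(self):
        w = synth_swd_waveform(9.0, 9, 0.3, FS)
        f, p = _welch_default(np.tile(w, 10), FS)
        assert abs(f[np.argmax(p)] - 9.0) <= 1.0

    @pytest.mark.parametrize("n_cycles", [3, 6, 9, 12])
    def test_cycle_count_roundtrip(self, n_cycles):
        w = synth_swd_waveform(9.0, n_cycles, 0.3, FS)
        assert count_cycles(w) == n_cycles
        assert count_cycles(bandpass(w, FS)) == n_cycles


class TestBackground:
    def test_sleep_has_more_delta_than_movement(self):
        cfg = SessionConfig()
        rng = np.random.default_rng(0)
        sleep = synth_background("sleep", 60.0, cfg, rng)
        move = synth_background("movement", 60.0, cfg, rng)
        sleep = sleep / sleep.std()
        move = move / move.std()  # matched total variance
        f1, p1 = _welch_default(sleep, FS)
        f2, p2 = _welch_default(move, FS)
        delta = (f1 >= 1) & (f1 <= 4)
        assert p1[delta].sum() > p2[delta].sum()

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            synth_background("limbo", 10.0, SessionConfig(), np.random.default_rng(0))

    def test_zero_levels_give_zero_segment(self):
        cfg = SessionConfig(
            background_levels={
                "sleep": {"pink": 0, "delta": 0, "theta": 0, "spindle": 0, "broadband": 0}
            }
        )
        seg = synth_background("sleep", 5.0, cfg, np.random.default_rng(0))
        assert np.all(seg == 0.0)

    def test_spindle_stays_below_detection_threshold(self, short_session):
        # a 12-15 Hz packet at default amplitude cannot cross the
        # envelope threshold of a default session, so it can never
        # satisfy the SWD inclusion predicate
        _, eeg, _, _ = short_session
        signal = eeg.channel(0)
        ss = build_sweep_set(signal, eeg.fs)
        events = detect_swds(signal, eeg.fs, ss.artifact, DetectorConfig())
        thr = events.attrs["threshold_mv"]
        rng = np.random.default_rng(0)
        packets = _spindle_train(int(60 * FS), FS, 0.05, rng, rate_per_min=30.0)
        peak_env = envelope(bandpass(packets, FS)).max()
        assert peak_env < thr


class TestEventPlacement:
    def test_poisson_rate_calibration(self):
        # 100/h configured in sleep; across 200 seeds the mean recovered
        # rate stays within 3 SE of the target (Poisson law)
        schedule = [("movement", 60.0), ("immobility", 3690.0)]
        rates = []
        for seed in range(200):
            cfg = SessionConfig(
                duration_s=3750.0,
                state_schedule=schedule,
                swd_rate_per_state={"sleep": 100.0},
                seed=seed,
            )
            gt, _ = simulate_ground_truth(cfg)
            hours = ((gt.sweep_states == "sleep") & ~gt.artifact_flags()).sum() * 10 / 3600
            rates.append(len(gt.events) / hours)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - 100.0) < 3 * se

    def test_events_avoid_artifacts_and_movement(self):
        cfg = SessionConfig(duration_s=1200.0, seed=4, artifact_sweep_fraction=0.1)
        gt, _ = simulate_ground_truth(cfg)
        flags = gt.artifact_flags()
        fps = cfg.video_fps
        for _, ev in gt.events.iterrows():
            assert not flags[int(ev.start_s // 10)]
            frames = gt.frame_states[int(ev.start_s * fps) : int(np.ceil(ev.end_s * fps))]
            assert not np.any(frames == MOVEMENT)

    def test_events_non_overlapping_and_in_session(self):
        cfg = SessionConfig(duration_s=1200.0, seed=5)
        gt, _ = simulate_ground_truth(cfg)
        ev = gt.events.sort_values("start_s")
        assert (ev["end_s"] > ev["start_s"]).all()
        assert ev["start_s"].min() >= 0 and ev["end_s"].max() <= 1200.0
        gaps = ev["start_s"].to_numpy()[1:] - ev["end_s"].to_numpy()[:-1]
        assert np.all(gaps >= 0)

    def test_event_state_matches_frame_state_at_onset(self):
        cfg = SessionConfig(duration_s=1200.0, seed=6)
        gt, _ = simulate_ground_truth(cfg)
        fps = cfg.video_fps
        for _, ev in gt.events.iterrows():
            frame = gt.frame_states[int(ev.start_s * fps)]
            if ev.state == "sleep":
                assert frame == SLEEP
            else:
                assert frame != MOVEMENT


class TestTrajectoryGlitches:
    def test_single_turnback_modifies_exactly_one_point(self):
        cfg = SessionConfig(
            duration_s=120.0,
            state_schedule=[("movement", 120.0)],
            seed=0,
            glitch_rates={"sharp_turn": 1.0, "jump": 0.0},
        )
        found = False
        for seed in range(10):
            traj, gl = synth_trajectory(
                cfg.state_schedule, cfg, np.random.default_rng(seed), return_glitches=True
            )
            if len(gl["sharp_turn"]) != 1:
                continue
            found = True
            out = correct_sharp_turns(traj)
            moved = np.flatnonzero(
                np.hypot(out.x_cm - traj.x_cm, out.y_cm - traj.y_cm) > 1e-9
            )
            assert moved.tolist() == gl["sharp_turn"]
        assert found

    def test_jump_glitch_bypassed(self):
        cfg = SessionConfig(
            duration_s=60.0,
            state_schedule=[("movement", 60.0)],
            seed=0,
            glitch_rates={"sharp_turn": 0.0, "jump": 2.0},
        )
        traj, gl = synth_trajectory(
            cfg.state_schedule, cfg, np.random.default_rng(1), return_glitches=True
        )
        assert gl["jump"]
        out, accepted = correct_jumps(traj, return_accepted=True)
        for k in gl["jump"]:
            assert k not in accepted
            # replaced by a nearby interpolated location, not the spurious point
            assert np.hypot(out.x_cm[k] - traj.x_cm[k], out.y_cm[k] - traj.y_cm[k]) > 5.0

    def test_glitch_free_cleaning_is_near_identity(self):
        cfg = SessionConfig(duration_s=300.0, seed=2, glitch_rates={})
        traj = synth_trajectory(
            [("movement", 150.0), ("immobility", 150.0)], cfg, np.random.default_rng(2)
        )
        cleaned = correct_jumps(correct_sharp_turns(traj))
        d = np.hypot(cleaned.x_cm - traj.x_cm, cleaned.y_cm - traj.y_cm)
        # nothing to correct: displacements stay at jitter scale for
        # almost every frame (nearest-of-4 may skip the odd genuine
        # point on a tight curve)
        assert np.quantile(d, 0.995) < 0.05
        assert (d > 0.05).mean() < 0.005

    def test_positions_inside_arena_except_jumps(self):
        cfg = SessionConfig(duration_s=300.0, seed=7)
        traj, gl = synth_trajectory(
            [("movement", 200.0), ("immobility", 100.0)],
            cfg,
            np.random.default_rng(7),
            return_glitches=True,
        )
        r = np.hypot(traj.x_cm, traj.y_cm)
        outside = np.flatnonzero(r > cfg.arena_radius_cm)
        assert set(outside.tolist()) <= set(gl["jump"])
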