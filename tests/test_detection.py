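"""Envelope-threshold SWD detection and state-normalized statistics."""

import numpy as np
import pandas as pd
import pytest

from swdscope.detection import (
    DetectorConfig,
    assign_event_states,
    bandpass,
    count_cycles,
    detect_candidates,
    detect_swds,
    envelope,
    inclusion_predicate,
    per_state_rates,
    review_roundtrip,
)
from swdscope.staging import SweepLabels
from swdscope.synthetic import synth_background, SessionConfig

FS = 2000.0


def sweep_labels(states):
    states = np.asarray(states, dtype=object)
    idx = np.arange(states.size)
    return SweepLabels(idx, idx * 10.0, states)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 9.0 * t)
        y = bandpass(x, FS)
        mid = slice(int(2 * FS), int(18 * FS))
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated_40db(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass(x, FS)
        mid = slice(int(2 * FS), int(18 * FS))
        assert np.abs(y[mid]).max() < 10 ** (-40 / 20)

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(int(FS)), FS), 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 40.0)


class TestEnvelope:
    def test_constant_tone_envelope_equals_amplitude(self):
        t = np.arange(int(10 * FS)) / FS
        x = 0.7 * np.sin(2 * np.pi * 9.0 * t)
        env = envelope(x)
        mid = slice(int(FS), int(9 * FS))
        assert np.allclose(env[mid], 0.7, rtol=0.02)

    def test_tracks_amplitude_modulator(self):
        t = np.arange(int(10 * FS)) / FS
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        x = mod * np.sin(2 * np.pi * 9.0 * t)
        env = envelope(x)
        mid = slice(int(FS), int(9 * FS))
        rms = np.sqrt(np.mean((env[mid] - mod[mid]) ** 2)) / np.sqrt(np.mean(mod[mid] ** 2))
        assert rms < 0.05

    def test_zero_envelope(self):
        assert np.allclose(envelope(np.zeros(1000)), 0.0)


class TestCandidates:
    def test_everything_below_threshold_empty(self):
        rng = np.random.default_rng(0)
        env = np.abs(rng.normal(1.0, 0.01, int(10 * FS)))
        cands, thr = detect_candidates(env, FS, k_sd=10.0)
        assert cands == []

    def test_injected_burst_found(self):
        rng = np.random.default_rng(1)
        env = np.abs(rng.normal(0.1, 0.01, int(30 * FS)))
        a, b = int(10 * FS), int(11 * FS)
        env[a:b] = 1.0
        cands, thr = detect_candidates(env, FS)
        assert len(cands) == 1
        s, e = cands[0]
        covered = max(0, min(e, b) - max(s, a)) / (b - a)
        assert covered >= 0.8

    def test_candidate_count_monotone_in_k_sd(self, short_session):
        # sweeping the documented 1.8-3.4 SD threshold range over a real
        # session envelope never increases the candidate count
        _, eeg, _, _ = short_session
        env = envelope(bandpass(eeg.channel(0), FS))
        counts = [len(detect_candidates(env, FS, k_sd=k)[0]) for k in np.arange(1.8, 3.45, 0.2)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_envelope_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            cands, _ = detect_candidates(np.ones(1000), FS)
        assert cands == []

    def test_gain_invariance(self):
        rng = np.random.default_rng(3)
        env_sig = rng.standard_normal(int(60 * FS)) * 0.05
        env_sig[int(20 * FS) : int(20.8 * FS)] += 1.0
        c1, _ = detect_candidates(envelope(env_sig), FS)
        c2, _ = detect_candidates(envelope(env_sig * 7.3), FS)
        assert c1 == c2


class TestCycleCounting:
    def test_noise_segment_counts_low(self, short_session):
        # with the detector's threshold-derived prominence floor, pure
        # background at default amplitude yields at most a couple cycles
        _, eeg, _, _ = short_session
        events = detect_swds(eeg.channel(0), eeg.fs)
        floor = 0.5 * events.attrs["threshold_mv"]
        cfg = SessionConfig()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seg = synth_background("sleep", 0.5, cfg, rng)
            assert count_cycles(bandpass(seg, FS), min_prominence=floor) <= 2

    def test_zero_segment(self):
        assert count_cycles(np.zeros(500)) == 0
        assert count_cycles(np.zeros(0)) == 0


class TestInclusionPredicate:
    @pytest.mark.parametrize(
        "duration_ms,n_cycles,expected",
        [
            (400.0, 3, False),  # both boundaries strict
            (401.0, 3, True),
            (300.0, 4, True),  # OR-rule
            (400.0, 4, True),
            (100.0, 3, False),
            (500.0, 0, True),
        ],
    )
    def test_strict_or_rule(self, duration_ms, n_cycles, expected):
        assert inclusion_predicate(duration_ms, n_cycles) is expected


class TestReview:
    def _events(self):
        return pd.DataFrame(
            {
                "event_id": [0, 1, 2, 3],
                "start_s": [1.0, 2.0, 3.0, 4.0],
                "end_s": [1.5, 2.5, 3.5, 4.5],
                "passes": [True, True, True, False],
                "accepted": [True, True, True, False],
            }
        )

    def test_automated_mode_accepts_predicate(self):
        out = review_roundtrip(self._events(), None)
        assert out["accepted"].tolist() == [True, True, True, False]

    def test_reject_all(self):
        out = review_roundtrip(self._events(), {i: False for i in range(4)})
        assert not out["accepted"].any()

    def test_partial_accept(self):
        out = review_roundtrip(self._events(), {0: True, 1: False, 2: True, 3: True})
        # id 3 fails the predicate regardless of the rater
        assert out["accepted"].tolist() == [True, False, True, False]

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            review_roundtrip(self._events(), {9: True})


class TestStateAssignment:
    def test_event_takes_sweep_state(self):
        labels = sweep_labels(["movement", "sleep", "waking_immobility"])
        ev = pd.DataFrame({"event_id": [0], "start_s": [15.0], "end_s": [16.0], "accepted": [True]})
        out = assign_event_states(ev, labels)
        assert out.loc[0, "state"] == "sleep"

    def test_boundary_spanning_event_uses_start_sweep(self):
        labels = sweep_labels(["sleep", "movement"])
        ev = pd.DataFrame({"event_id": [0], "start_s": [9.5], "end_s": [10.5], "accepted": [True]})
        assert assign_event_states(ev, labels).loc[0, "state"] == "sleep"

    def test_event_in_artifact_sweep_dropped(self):
        labels = sweep_labels(["sleep", "sleep"])
        flags = np.array([False, True])
        ev = pd.DataFrame({"event_id": [0], "start_s": [12.0], "end_s": [13.0], "accepted": [True]})
        assert len(assign_event_states(ev, labels, flags)) == 0

    def test_event_outside_range_errors(self):
        labels = sweep_labels(["sleep"])
        ev = pd.DataFrame({"event_id": [0], "start_s": [25.0], "end_s": [26.0], "accepted": [True]})
        with pytest.raises(IndexError):
            assign_event_states(ev, labels)


class TestRates:
    def test_rate_arithmetic(self):
        # 50 events in half an hour of sleep -> 100 events/h
        labels = sweep_labels(["sleep"] * 180)
        ev = pd.DataFrame(
            {
                "event_id": np.arange(50),
                "start_s": np.arange(50) * 30.0,
                "end_s": np.arange(50) * 30.0 + 1.0,
                "accepted": True,
                "state": "sleep",
            }
        )
        res = per_state_rates(ev, labels)
        assert res.loc["sleep", "hours_in_state"] == pytest.approx(0.5)
        assert res.loc["sleep", "swd_count_per_hour"] == pytest.approx(100.0)
        assert res.loc["sleep", "total_swd_s_per_hour"] == pytest.approx(100.0)
        assert res.loc["sleep", "mean_single_duration_s"] == pytest.approx(1.0)

    def test_no_events_zero_rates_missing_mean(self):
        labels = sweep_labels(["sleep"] * 10 + ["waking_immobility"] * 10)
        ev = pd.DataFrame(columns=["event_id", "start_s", "end_s", "accepted", "state"])
        res = per_state_rates(ev, labels)
        assert res.loc["sleep", "swd_count_per_hour"] == 0.0
        assert np.isnan(res.loc["sleep", "mean_single_duration_s"])

    def test_zero_hours_is_missing_not_zero(self):
        labels = sweep_labels(["sleep"] * 10)
        ev = pd.DataFrame(columns=["event_id", "start_s", "end_s", "accepted", "state"])
        res = per_state_rates(ev, labels)
        assert np.isnan(res.loc["mixed", "swd_count_per_hour"])

    def test_artifact_sweeps_do_not_count_as_state_time(self):
        labels = sweep_labels(["sleep"] * 10)
        flags = np.array([True] * 5 + [False] * 5)
        ev = pd.DataFrame(columns=["event_id", "start_s", "end_s", "accepted", "state"])
        res = per_state_rates(ev, labels, flags)
        assert res.loc["sleep", "hours_in_state"] == pytest.approx(50 / 3600)


class TestFullDetector:
    def test_session_gain_invariance(self, short_session):
        _, eeg, _, _ = short_session
        x = eeg.channel(0)[: int(120 * FS)]
        e1 = detect_swds(x, FS)
        e2 = detect_swds(x * 3.7, FS)
        assert e1["start_s"].tolist() == e2["start_s"].tolist()
        assert e1["end_s"].tolist() == e2["end_s"].tolist()
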