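"""Rule-boundary recovery and synthetic-performance benchmarks.

Each boundary function rediscovers one of the pipeline's printed
thresholds by exhaustively sweeping the corresponding predicate — the
same way an auditor would probe a black box — and returns
``(value, n_probes)``.  The performance benchmarks run the detector and
the rate-normalization chain against generator ground truth.
"""

from __future__ import annotations

import numpy as np

from .detection import DetectorConfig, assign_event_states, detect_swds, inclusion_predicate, per_state_rates
from .preprocess import build_sweep_set, qualify_channel
from .spectral import merged_swd_psd, state_psd_relative, PSDResult
from .staging import (
    IMMOBILITY,
    MOVEMENT,
    SLEEP,
    Trajectory,
    apply_sleep_rule,
    assign_sweeps,
    classify_frames,
    correct_sharp_turns,
    despike_single_movement,
    instant_speed,
)
from .synthetic import SessionConfig, simulate_ground_truth, simulate_session

__all__ = [
    "sleep_latency_boundary",
    "immobility_speed_boundary",
    "inclusion_duration_boundary",
    "dominance_boundary",
    "relative_psd_sum",
    "channel_qualification_boundary",
    "sharp_turn_angle_boundary",
    "detector_performance",
    "sleep_rate_recovery",
]


def sleep_latency_boundary(fps: float = 20.0):
    """Seconds from immobility onset to the first sleep-labeled frame.

    Built from a 10-s movement + 60-s zero-speed trajectory run through
    classification, despiking and the sleep rule.
    """
    n_move = int(10 * fps)
    n_still = int(60 * fps)
    n = n_move + n_still
    t = np.arange(n) / fps
    x = np.concatenate([np.arange(n_move) * 0.1, np.full(n_still, (n_move - 1) * 0.1)])
    traj = Trajectory(t, x, np.zeros(n), fps)
    speeds = instant_speed(traj)
    labels = despike_single_movement(classify_frames(speeds))
    labels = apply_sleep_rule(labels, fps)
    onset = t[np.flatnonzero(labels != MOVEMENT)[0]]
    first_sleep = t[np.flatnonzero(labels == SLEEP)[0]]
    return float(first_sleep - onset), n


def immobility_speed_boundary():
    """Largest constant speed still classified immobility, 0..1 cm/s by 0.01."""
    speeds = np.arange(101) / 100.0
    labels = classify_frames(speeds)
    return float(speeds[labels == IMMOBILITY].max()), speeds.size


def inclusion_duration_boundary():
    """Largest duration rejected by the SWD rule at exactly three cycles."""
    durations = np.arange(100, 801)
    rejected = [d for d in durations if not inclusion_predicate(float(d), 3)]
    return float(max(rejected)), durations.size


def dominance_boundary(n_frames: int = 200):
    """Largest movement-frame percentage still labeled mixed in one sweep."""
    fps = n_frames / 10.0
    best = None
    for m in range(n_frames + 1):
        labels = np.concatenate(
            [np.full(m, MOVEMENT, dtype=np.int8), np.full(n_frames - m, IMMOBILITY, dtype=np.int8)]
        )
        sweep = assign_sweeps(labels, fps)
        if sweep.state[0] == "mixed":
            best = m
    return 100.0 * best / n_frames, n_frames + 1


def relative_psd_sum(seed: int = 0):
    """Sum of relative-PSD bins over 1-30 Hz for a random positive spectrum."""
    rng = np.random.default_rng(seed)
    absolute = PSDResult(np.arange(1, 101), rng.uniform(0.1, 10.0, 100), "absolute", 1)
    rel = state_psd_relative(absolute)
    return float(rel.band(1, 30).sum()), 100


def channel_qualification_boundary():
    """Smallest noisy-sweep count that disqualifies a channel, 0..120."""
    counts = np.arange(121)
    disqualified = [c for c in counts if not qualify_channel(np.ones(c, dtype=bool))]
    return float(min(disqualified)), counts.size


def sharp_turn_angle_boundary():
    """Largest turn angle (deg) leaving a 3-point path unmodified, 0..180."""
    largest = None
    for deg in range(181):
        theta = np.deg2rad(deg)
        p0 = np.array([0.0, 0.0])
        p1 = np.array([1.0, 0.0])
        p2 = p1 + np.array([np.cos(theta), np.sin(theta)])
        traj = Trajectory(np.arange(3) / 20.0, [p0[0], p1[0], p2[0]], [p0[1], p1[1], p2[1]], 20.0)
        out = correct_sharp_turns(traj)
        if np.array_equal(out.points(), traj.points()):
            largest = deg
    return float(largest), 181


def detector_performance(seed: int = 0, duration_s: float = 1800.0, k_sd: float = 2.5):
    """Recall and precision of the detector on one synthetic session.

    Events match by >=50% temporal overlap (intersection over the
    shorter of the two events); SWD amplitude is the generator default
    (3x background SD).
    """
    cfg = SessionConfig(duration_s=duration_s, seed=seed, glitch_rates={})
    eeg, _, gt = simulate_session(cfg)
    signal = eeg.channel(0)
    sweep_set = build_sweep_set(signal, eeg.fs)
    events = detect_swds(signal, eeg.fs, sweep_set.artifact, DetectorConfig(k_sd=k_sd))
    det = events[events["accepted"]]

    def overlap_frac(a0, a1, b0, b1):
        inter = max(0.0, min(a1, b1) - max(a0, b0))
        return inter / min(a1 - a0, b1 - b0)

    true = list(zip(gt.events["start_s"], gt.events["end_s"]))
    found = list(zip(det["start_s"], det["end_s"]))
    matched_true = sum(
        1 for t0, t1 in true if any(overlap_frac(t0, t1, d0, d1) >= 0.5 for d0, d1 in found)
    )
    matched_det = sum(
        1 for d0, d1 in found if any(overlap_frac(t0, t1, d0, d1) >= 0.5 for t0, t1 in true)
    )
    recall = matched_true / len(true) if true else np.nan
    precision = matched_det / len(found) if found else np.nan
    return recall, precision, len(true), len(found)


def sleep_rate_recovery(seed: int = 0, n_seeds: int = 100, rate: float = 100.0):
    """Recovered sleep SWD rate across seeds (generator + normalization).

    Each replicate schedules ~1 h of deep immobility, places true events
    at the configured rate, and recovers count/hour through the
    state-normalization operator using the true sweep labels and
    artifact mask.  Returns (mean rate, SE of the mean, n_seeds).
    """
    schedule = [("movement", 60.0), ("immobility", 3600.0 + 90.0)]
    duration = sum(d for _, d in schedule)
    recovered = []
    for s in range(n_seeds):
        cfg = SessionConfig(
            duration_s=duration,
            state_schedule=schedule,
            swd_rate_per_state={"sleep": rate},
            seed=seed + s,
        )
        gt, _ = simulate_ground_truth(cfg)
        ev = gt.events.assign(accepted=True)

        class _Sweeps:
            state = gt.sweep_states
            sweep_s = 10.0

        rates = per_state_rates(ev, _Sweeps(), gt.artifact_flags())
        recovered.append(rates.loc["sleep", "swd_count_per_hour"])
    recovered = np.asarray(recovered)
    return float(recovered.mean()), float(recovered.std(ddof=1) / np.sqrt(n_seeds)), n_seeds
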