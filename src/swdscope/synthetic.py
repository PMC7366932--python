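"""Synthetic video-EEG sessions with known ground truth.

The generator emulates a 3-h single-mouse recording session: a
state-dependent background EEG (slow-wave sleep with delta activity and
intermittent 12-15 Hz sleep spindles, REM-like theta subsegments, a
low-amplitude waking background), injected spike-wave trains with a ~9 Hz
fundamental, broadband artifact sweeps, and a ~20 fps tracking
trajectory with movement/immobility bout structure plus the two classic
tracking glitches (sharp turn-backs and star-shaped single-frame jumps).

Every random draw flows from one seeded generator, so an identical
configuration reproduces the session bit for bit.  Event placement is a
thinned Poisson process per behavioral state with a 2-s refractory gap,
and events are never placed inside artifact sweeps or movement frames
(SWDs seldom occur while the animal moves; the generator enforces this
as a hard constraint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import staging
from .preprocess import ARTIFACT_THRESHOLD_MV2HZ, EEGRecord, sweep_summed_power
from .staging import IMMOBILITY, MOVEMENT, SLEEP, Trajectory, apply_sleep_rule, assign_sweeps

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "default_state_schedule",
    "default_background_levels",
    "synth_swd_waveform",
    "synth_background",
    "synth_trajectory",
    "simulate_ground_truth",
    "simulate_session",
]

SWEEP_S = 10.0
REFRACTORY_S = 2.0
EVENT_STATES = ("sleep", "waking_immobility", "mixed")


def default_background_levels() -> dict:
    """Per-state component amplitudes (mV, std except spindle peak).

    No reference amplitudes exist for these recordings; the levels are
    free generator parameters chosen to mimic a mouse cortical
    screw-electrode EEG:
    delta-dominated slow-wave sleep with spindle bursts, theta-tinged
    waking, and a common 1/f floor.
    """
    return {
        "sleep": {"pink": 0.05, "delta": 0.10, "theta": 0.03, "spindle": 0.05, "broadband": 0.01},
        "immobility": {"pink": 0.05, "delta": 0.04, "theta": 0.03, "spindle": 0.0, "broadband": 0.015},
        "movement": {"pink": 0.05, "delta": 0.03, "theta": 0.04, "spindle": 0.0, "broadband": 0.02},
    }


@dataclass
class SessionConfig:
    """Everything needed to synthesize one recording session."""

    duration_s: float = 10800.0  # 3-h session
    video_fps: float = 20.0
    eeg_fs: float = 2000.0
    arena_radius_cm: float = 9.25  # 18.5-cm circular frame
    state_schedule: list | None = None  # [(state, duration_s)], movement/immobility
    swd_rate_per_state: dict = field(
        default_factory=lambda: {"sleep": 100.0, "waking_immobility": 100.0, "mixed": 100.0}
    )
    swd_fundamental_hz: float = 9.0
    swd_cycles_range: tuple = (4, 12)
    swd_amplitude_mv: float | None = None  # None -> 3x background SD
    background_levels: dict = field(default_factory=default_background_levels)
    glitch_rates: dict = field(default_factory=lambda: {"sharp_turn": 0.5, "jump": 0.5})  # /min
    artifact_sweep_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.video_fps <= 0 or self.eeg_fs <= 0:
            raise ValueError("durations and rates must be positive")
        if not (7.0 <= self.swd_fundamental_hz <= 23.0):
            raise ValueError("swd_fundamental_hz must lie inside the 7-23 Hz detection band")
        if any(v < 0 for v in self.swd_rate_per_state.values()):
            raise ValueError("SWD rates must be non-negative")
        if any(v < 0 for v in self.glitch_rates.values()):
            raise ValueError("glitch rates must be non-negative")
        if not (0 <= self.artifact_sweep_fraction < 1):
            raise ValueError("artifact_sweep_fraction must be in [0, 1)")
        lo, hi = self.swd_cycles_range
        if lo < 1 or hi < lo:
            raise ValueError("swd_cycles_range must satisfy 1 <= min <= max")
        if self.state_schedule is not None:
            total = sum(d for _, d in self.state_schedule)
            if not np.isclose(total, self.duration_s):
                raise ValueError(
                    f"state_schedule durations sum to {total}, expected {self.duration_s}"
                )
            for s, _ in self.state_schedule:
                if s not in ("movement", "immobility"):
                    raise ValueError(f"unknown schedule state {s!r}")


@dataclass
class GroundTruth:
    """What the generator actually put into the session."""

    events: pd.DataFrame  # start_s, end_s, n_cycles, state
    frame_states: np.ndarray  # int8 per frame (movement/immobility/sleep)
    sweep_states: np.ndarray  # str per 10-s sweep
    artifact_sweeps: np.ndarray  # sweep indices
    schedule: list

    def artifact_flags(self, n_sweeps: int | None = None) -> np.ndarray:
        n = n_sweeps if n_sweeps is not None else self.sweep_states.size
        flags = np.zeros(n, dtype=bool)
        flags[self.artifact_sweeps[self.artifact_sweeps < n]] = True
        return flags


def default_state_schedule(duration_s: float, rng: np.random.Generator) -> list:
    """Bout schedule mimicking a typical session.

    Roughly the first sixth of the session is exploration
    (movement-dominant), the middle half alternates immobility and short
    walks, and the final third is long immobility (hence mostly sleep).
    """
    phases = [
        (duration_s / 6.0, (15.0, 45.0), (5.0, 20.0)),  # explore: long moves, short stops
        (duration_s / 2.0, (5.0, 20.0), (30.0, 120.0)),  # alternation
        (duration_s / 3.0, (3.0, 10.0), (120.0, 400.0)),  # sleep-dominant
    ]
    schedule = []
    move = True
    for phase_len, move_rng, still_rng in phases:
        t = 0.0
        while t < phase_len:
            lo, hi = move_rng if move else still_rng
            d = float(rng.uniform(lo, hi))
            d = min(d, phase_len - t)
            schedule.append(("movement" if move else "immobility", d))
            t += d
            move = not move
    # exact total: absorb any float residue into the last bout
    total = sum(d for _, d in schedule)
    state, d = schedule[-1]
    schedule[-1] = (state, d + (duration_s - total))
    return schedule


def synth_swd_waveform(
    fundamental_hz: float, n_cycles: int, amplitude_mv: float, fs: float
) -> np.ndarray:
    """One spike-wave train: slow sinusoid + one sharp spike per cycle.

    Each cycle is a sinusoid at the fundamental carrying a Gaussian
    spike (FWHM = period/8) at the phase of the slow-wave maximum, so
    the number of countable spikes equals ``n_cycles``.  The segment
    lasts ``n_cycles / fundamental_hz`` seconds and peaks at
    ``amplitude_mv``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not (7.0 <= fundamental_hz <= 23.0):
        raise ValueError("fundamental must lie inside the 7-23 Hz band")
    period = 1.0 / fundamental_hz
    n_samp = int(round(n_cycles * period * fs))
    t = np.arange(n_samp) / fs
    # slow-wave peaks at (k + 1/2) * period, i.e. away from the edges
    slow = np.cos(2 * np.pi * fundamental_hz * (t - 0.5 * period))
    sigma = (period / 8.0) / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM = period/8
    spike = np.zeros(n_samp)
    for k in range(n_cycles):
        c = (k + 0.5) * period
        spike += np.exp(-0.5 * ((t - c) / sigma) ** 2)
    w = slow + 1.5 * spike
    return amplitude_mv * w / float(w.max())


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator, order: int = 8
) -> np.ndarray:
    # steep (order-8, zero-phase) edges keep out-of-band leakage of the
    # rhythmic components away from the 7-23 Hz detection band
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _spindle_train(
    n: int, fs: float, peak_mv: float, rng: np.random.Generator, rate_per_min: float = 4.0
) -> np.ndarray:
    """Intermittent 12-15 Hz Hann-windowed packets."""
    x = np.zeros(n)
    n_spindles = rng.poisson(rate_per_min * (n / fs) / 60.0)
    for _ in range(n_spindles):
        dur = float(rng.uniform(0.4, 1.0))
        m = int(round(dur * fs))
        if m < 4 or m >= n:
            continue
        start = int(rng.integers(0, n - m))
        freq = float(rng.uniform(12.0, 15.0))
        tt = np.arange(m) / fs
        packet = np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
        packet *= np.hanning(m)
        x[start : start + m] += peak_mv * packet
    return x


def synth_background(
    state: str, duration_s: float, config: SessionConfig, rng: np.random.Generator
) -> np.ndarray:
    """State-dependent background EEG segment (mV).

    Sleep mixes 1/f noise, delta (1-4 Hz) and intermittent spindle
    bursts, with REM-like theta subsegments replacing roughly 15% of
    long sleep stretches; waking states are a low-amplitude 1/f +
    broadband mixture with some theta.  Zero component amplitudes yield
    an exactly zero segment.
    """
    if state not in config.background_levels:
        raise ValueError(f"unknown behavioral state {state!r}")
    lv = config.background_levels[state]
    fs = config.eeg_fs
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    x = np.zeros(n)
    if all(v == 0 for v in lv.values()):
        return x
    if lv.get("pink", 0) > 0 and n > 8:
        x += lv["pink"] * _pink_noise(n, rng)
    if lv.get("delta", 0) > 0 and n > 64:
        x += lv["delta"] * _band_noise(n, fs, 1.0, 4.0, rng)
    if lv.get("theta", 0) > 0 and n > 64 and state != "sleep":
        x += lv["theta"] * _band_noise(n, fs, 6.0, 9.0, rng)
    if lv.get("broadband", 0) > 0:
        x += lv["broadband"] * rng.standard_normal(n)
    if lv.get("spindle", 0) > 0 and n > 64:
        x += _spindle_train(n, fs, lv["spindle"], rng)
    if state == "sleep" and lv.get("theta", 0) > 0 and duration_s > 60.0 and n > 64:
        # REM-like theta subsegments: ~15% of long sleep, 20-40 s chunks
        t = 0.0
        theta = lv["theta"]
        while t < duration_s - 40.0:
            gap = float(rng.uniform(100.0, 250.0))
            rem_dur = float(rng.uniform(20.0, 40.0))
            a = int(round((t + gap) * fs))
            b = min(int(round((t + gap + rem_dur) * fs)), n)
            if a >= n:
                break
            m = b - a
            if m > 64:
                x[a:b] = lv["pink"] * _pink_noise(m, rng) + 1.5 * theta * _band_noise(
                    m, fs, 6.0, 9.0, rng
                )
            t += gap + rem_dur
    return x


def _frame_ground_truth(schedule: list, fps: float, n_frames: int) -> np.ndarray:
    """Per-frame movement/immobility labels, then the 31st-second sleep rule."""
    labels = np.empty(n_frames, dtype=np.int8)
    pos = 0
    for state, dur in schedule:
        m = int(round(dur * fps))
        labels[pos : min(pos + m, n_frames)] = MOVEMENT if state == "movement" else IMMOBILITY
        pos += m
    if pos < n_frames:
        labels[pos:] = labels[pos - 1] if pos else IMMOBILITY
    return apply_sleep_rule(labels, fps)


def synth_trajectory(
    schedule: list,
    config: SessionConfig,
    rng: np.random.Generator,
    return_glitches: bool = False,
):
    """Tracking trajectory for a bout schedule, with injected glitches.

    Movement bouts are a correlated random walk at 1.5-6 cm/s reflected
    at the arena wall; immobility bouts jitter around an anchor with
    sub-threshold instant speeds.  Sharp-turn glitches displace a single
    movement frame so the turning angle exceeds 135 deg; jump glitches
    send a single frame to one fixed spurious point outside the arena
    (star-shaped tracking error).
    """
    fps = config.video_fps
    n_frames = int(round(config.duration_s * fps))
    time_s = np.arange(n_frames) / fps
    pos = np.zeros((n_frames, 2))
    R = config.arena_radius_cm
    margin = 0.5
    p = np.array([0.0, 0.0])
    heading = float(rng.uniform(0, 2 * np.pi))
    i = 0
    bout_of_frame = np.empty(n_frames, dtype=np.int8)  # MOVEMENT / IMMOBILITY
    for state, dur in schedule:
        m = min(int(round(dur * fps)), n_frames - i)
        if m <= 0:
            continue
        if state == "movement":
            speeds = rng.uniform(1.5, 6.0, m)
            turns = rng.normal(0.0, 0.25, m)
            for j in range(m):
                heading += turns[j]
                step = speeds[j] / fps
                cand = p + step * np.array([np.cos(heading), np.sin(heading)])
                if np.hypot(*cand) > R - margin:
                    # steer toward the center gradually (<=80 deg/frame) so
                    # wall avoidance never looks like a tracking glitch
                    center_dir = float(np.arctan2(-p[1], -p[0]))
                    diff = (center_dir - heading + np.pi) % (2 * np.pi) - np.pi
                    heading += float(np.clip(diff, -1.4, 1.4))
                    cand = p + step * np.array([np.cos(heading), np.sin(heading)])
                    rad = np.hypot(*cand)
                    if rad > R - 0.1:
                        cand *= (R - 0.1) / rad
                p = cand
                pos[i + j] = p
            bout_of_frame[i : i + m] = MOVEMENT
        else:
            anchor = p.copy()
            jitter = rng.normal(0.0, 0.003, (m, 2))
            pos[i : i + m] = anchor + jitter
            bout_of_frame[i : i + m] = IMMOBILITY
            p = pos[i + m - 1].copy()
        i += m
    if i < n_frames:
        pos[i:] = p
        bout_of_frame[i:] = IMMOBILITY

    minutes = config.duration_s / 60.0
    glitches = {"sharp_turn": [], "jump": []}
    move_idx = np.flatnonzero(bout_of_frame == MOVEMENT)
    interior = move_idx[(move_idx > 2) & (move_idx < n_frames - 3)]
    n_turn = rng.poisson(config.glitch_rates.get("sharp_turn", 0.0) * minutes)
    if n_turn > 0 and interior.size:
        placed = 0
        candidates = rng.permutation(interior)
        for k in candidates:
            if placed >= n_turn:
                break
            d = pos[k + 1] - pos[k - 1]
            norm = np.hypot(*d)
            if norm == 0:
                continue
            # lateral spike 1.5x the local travel span: the turn at k lands
            # near 143 deg (sharp) while the angles at k-1 and k+1 stay
            # moderate, so exactly one point needs correction
            perp = np.array([-d[1], d[0]]) / norm
            old = pos[k].copy()
            pos[k] = 0.5 * (pos[k - 1] + pos[k + 1]) + 1.5 * norm * perp
            angles = [abs(staging._angle_at(pos, m)) for m in (k - 1, k, k + 1)]
            # keep only clean glitches: sharp exactly at k (a wall-steering
            # bend next door could otherwise also trip the correction)
            if angles[1] > 140.0 and angles[0] < 125.0 and angles[2] < 125.0:
                glitches["sharp_turn"].append(int(k))
                placed += 1
            else:
                pos[k] = old
        glitches["sharp_turn"].sort()
    n_jump = rng.poisson(config.glitch_rates.get("jump", 0.0) * minutes)
    if n_jump > 0 and n_frames > 4:
        spurious = np.array([R + 3.0, R + 3.0])  # fixed non-mouse point
        cand = rng.integers(2, n_frames - 2, size=n_jump)
        for k in np.unique(cand):
            pos[k] = spurious
            glitches["jump"].append(int(k))

    traj = Trajectory(time_s, pos[:, 0], pos[:, 1], fps)
    if return_glitches:
        return traj, glitches
    return traj


def _place_events(
    sweep_states: np.ndarray,
    artifact_flags: np.ndarray,
    frame_labels: np.ndarray,
    config: SessionConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Thinned Poisson placement of SWD events per behavioral state."""
    fps = config.video_fps
    fund = config.swd_fundamental_hz
    lo, hi = config.swd_cycles_range
    placed = []  # (start, end) occupied, with refractory
    rows = []

    def conflicts(s, e):
        for a, b in placed:
            if s < b + REFRACTORY_S and e > a - REFRACTORY_S:
                return True
        return False

    for state in EVENT_STATES:
        rate = float(config.swd_rate_per_state.get(state, 0.0))
        eligible = np.flatnonzero((sweep_states == state) & ~artifact_flags)
        hours = eligible.size * SWEEP_S / 3600.0
        if rate <= 0 or hours == 0:
            continue
        count = rng.poisson(rate * hours)
        for _ in range(count):
            n_cycles = int(rng.integers(lo, hi + 1))
            dur = n_cycles / fund
            for _attempt in range(200):
                sweep = int(rng.choice(eligible))
                start = sweep * SWEEP_S + float(rng.uniform(0.0, SWEEP_S - dur))
                end = start + dur
                if conflicts(start, end):
                    continue
                f0 = int(start * fps)
                f1 = min(int(np.ceil(end * fps)), frame_labels.size)
                if np.any(frame_labels[f0:f1] == MOVEMENT):
                    continue
                placed.append((start, end))
                rows.append(
                    {"start_s": start, "end_s": end, "n_cycles": n_cycles, "state": state}
                )
                break
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "n_cycles", "state"])
    return df.sort_values("start_s").reset_index(drop=True)


def simulate_ground_truth(config: SessionConfig):
    """Schedule, frame/sweep labels, artifact sweeps and true events.

    The EEG-free core of :func:`simulate_session`; useful when only the
    generator's event statistics are needed.  Uses the same draw order,
    so ground truth is identical whether or not EEG is synthesized.
    """
    rng = np.random.default_rng(config.seed)
    schedule = (
        list(config.state_schedule)
        if config.state_schedule is not None
        else default_state_schedule(config.duration_s, rng)
    )
    fps = config.video_fps
    n_frames = int(round(config.duration_s * fps))
    frame_labels = _frame_ground_truth(schedule, fps, n_frames)
    sweeps = assign_sweeps(frame_labels, fps, SWEEP_S)
    n_sweeps = len(sweeps)
    n_art = int(round(config.artifact_sweep_fraction * n_sweeps))
    artifact_sweeps = (
        np.sort(rng.choice(n_sweeps, size=n_art, replace=False))
        if n_art
        else np.empty(0, dtype=int)
    )
    flags = np.zeros(n_sweeps, dtype=bool)
    flags[artifact_sweeps] = True
    events = _place_events(np.asarray(sweeps.state, dtype=object), flags, frame_labels, config, rng)
    gt = GroundTruth(events, frame_labels, np.asarray(sweeps.state, dtype=object),
                     artifact_sweeps.astype(int), schedule)
    return gt, rng


def _synth_eeg(
    gt: GroundTruth, config: SessionConfig, rng: np.random.Generator
) -> EEGRecord:
    fs = config.eeg_fs
    fps = config.video_fps
    n = int(round(config.duration_s * fs))
    x = np.zeros(n)
    # background follows the ground-truth frame states (incl. sleep tails)
    labels = gt.frame_states
    name = {MOVEMENT: "movement", IMMOBILITY: "immobility", SLEEP: "sleep"}
    for a, b, val in staging._runs(labels):
        s0 = int(round(a / fps * fs))
        s1 = min(int(round(b / fps * fs)), n)
        if s1 > s0:
            x[s0:s1] = synth_background(name[val], (s1 - s0) / fs, config, rng)

    amp = config.swd_amplitude_mv
    if amp is None:
        amp = 3.0 * float(x.std())  # 3x background SD (study condition)
    for _, row in gt.events.iterrows():
        w = synth_swd_waveform(config.swd_fundamental_hz, int(row["n_cycles"]), amp, fs)
        a = int(round(row["start_s"] * fs))
        b = min(a + w.size, n)
        x[a:b] += w[: b - a]

    spp = int(round(SWEEP_S * fs))
    for s in gt.artifact_sweeps:
        a, b = s * spp, min((s + 1) * spp, n)
        if b - a < spp:
            continue
        burst = rng.standard_normal(b - a)
        p = sweep_summed_power(burst, fs)
        burst *= np.sqrt(2.5 * ARTIFACT_THRESHOLD_MV2HZ / p)  # >=2x the exclusion rule
        x[a:b] += burst

    left = 0.85 * x + 0.02 * rng.standard_normal(n)  # unanalyzed contralateral channel
    return EEGRecord(np.vstack([x, left]), fs, ["right", "left"])


def simulate_session(config: SessionConfig, with_eeg: bool = True):
    """Generate one labeled session.

    Returns ``(EEGRecord or None, Trajectory, GroundTruth)``.  Identical
    configurations (including the seed) give bitwise-identical outputs.
    """
    gt, rng = simulate_ground_truth(config)
    traj = synth_trajectory(gt.schedule, config, rng)
    eeg = _synth_eeg(gt, config, rng) if with_eeg else None
    return eeg, traj, gt
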