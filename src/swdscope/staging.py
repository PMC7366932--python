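"""Video-trajectory cleaning and rule-based behavioral staging.

The staging model assigns every ~20 fps video frame to movement,
immobility or sleep from the animal's instant speed alone, then labels
each 10-s sweep with the dominant state (or "mixed" when no state
dominates).  The rules, in fixed order:

1. sharp-turn correction: a turning angle beyond +/-135 deg between
   successive displacement vectors marks a tracking glitch; the middle
   point is replaced by the mean of itself and the next point;
2. jump correction: among the four points following the current one the
   nearest is accepted as the next realistic location, bypassed points
   are linearly interpolated;
3. trajectory smoothing (penalized least squares, GCV);
4. instant speed > 0.5 cm/s -> movement, otherwise immobility;
5. an isolated single movement frame flanked by >=10 immobility frames
   on each side is relabeled immobility;
6. within any immobility run longer than 30 s, frames from 30 s onward
   are relabeled sleep;
7. each 10-s sweep takes the state covering strictly more than 60% of
   its frames, otherwise it is a mixed (transition) sweep.

All threshold comparisons are strict, matching the wording of the rules
(speed *higher than* 0.5 cm/s, runs *longer than* 30 s, a state that
*exceeds* 60%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .smoothing import smooth1d_gcv

__all__ = [
    "MOVEMENT",
    "IMMOBILITY",
    "SLEEP",
    "FRAME_STATE_NAMES",
    "SWEEP_STATES",
    "Trajectory",
    "FrameStates",
    "SweepLabels",
    "correct_sharp_turns",
    "correct_jumps",
    "smooth_trajectory",
    "instant_speed",
    "classify_frames",
    "despike_single_movement",
    "apply_sleep_rule",
    "assign_sweeps",
    "stage_trajectory",
]

# frame-level states
MOVEMENT, IMMOBILITY, SLEEP = 0, 1, 2
FRAME_STATE_NAMES = {MOVEMENT: "movement", IMMOBILITY: "immobility", SLEEP: "sleep"}

# sweep-level states (frame immobility maps to waking immobility)
SWEEP_STATES = ("sleep", "waking_immobility", "movement", "mixed")
_FRAME_TO_SWEEP = {MOVEMENT: "movement", IMMOBILITY: "waking_immobility", SLEEP: "sleep"}

SPEED_THRESHOLD_CM_S = 0.5
SLEEP_LATENCY_S = 30.0
DOMINANCE = 0.6
SWEEP_S = 10.0
TURN_ANGLE_DEG = 135.0
# float guard so an exactly-135-deg turn built from rotation matrices is
# never corrected through round-off; far below the 1-deg rule granularity
_ANGLE_EPS_DEG = 1e-9


@dataclass
class Trajectory:
    """Tracked positions (cm) on a common time base (s)."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    fps: float = 20.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (self.time_s.size == self.x_cm.size == self.y_cm.size):
            raise ValueError("time_s, x_cm and y_cm must have equal length")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.time_s.size)

    def points(self) -> np.ndarray:
        return np.column_stack([self.x_cm, self.y_cm])


@dataclass
class FrameStates:
    """Per-frame behavioral labels and the speeds they derive from."""

    time_s: np.ndarray
    labels: np.ndarray  # int8 codes MOVEMENT/IMMOBILITY/SLEEP
    speed_cm_s: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.size != np.asarray(self.time_s).size:
            raise ValueError("label array length must equal frame count")


@dataclass
class SweepLabels:
    """Per-10-s-sweep behavioral state, tiling the session from t=0."""

    sweep_index: np.ndarray
    start_s: np.ndarray
    state: np.ndarray  # str entries from SWEEP_STATES
    sweep_s: float = SWEEP_S

    def __len__(self) -> int:
        return int(self.sweep_index.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sweep_index": self.sweep_index, "start_s": self.start_s, "state": self.state}
        )


def _angle_at(p: np.ndarray, m: int) -> float:
    """Signed turn angle (deg, in (-180, 180]) at middle point ``m``."""
    v1 = p[m] - p[m - 1]
    v2 = p[m + 1] - p[m]
    if (v1 == 0).all() or (v2 == 0).all():
        return 0.0
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def _turn_angles(p: np.ndarray) -> np.ndarray:
    v = np.diff(p, axis=0)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    dot = np.sum(v[:-1] * v[1:], axis=1)
    ang = np.degrees(np.arctan2(cross, dot))
    # stationary segments carry no direction: no turn
    zero = (np.all(v[:-1] == 0, axis=1)) | (np.all(v[1:] == 0, axis=1))
    ang[zero] = 0.0
    return ang


def correct_sharp_turns(traj: Trajectory, angle_thresh_deg: float = TURN_ANGLE_DEG) -> Trajectory:
    """Remove unrealistically sharp turn-backs from a trajectory.

    Scanning forward, wherever the signed turning angle between
    consecutive displacement vectors is strictly beyond
    ``+/-angle_thresh_deg``, the middle point is replaced by the mean of
    itself and the next point.  Corrections are applied to the working
    copy, so later angles see earlier fixes.
    """
    n = len(traj)
    if n < 3:
        warnings.warn("fewer than 3 frames: sharp-turn correction skipped")
        return Trajectory(traj.time_s.copy(), traj.x_cm.copy(), traj.y_cm.copy(), traj.fps)
    p = traj.points().copy()
    ang = _turn_angles(p)  # ang[k] is the turn at middle point k+1
    thresh = angle_thresh_deg + _ANGLE_EPS_DEG
    for k in range(n - 2):
        if abs(ang[k]) > thresh:
            m = k + 1
            p[m] = 0.5 * (p[m] + p[m + 1])
            if k + 1 < n - 2:
                ang[k + 1] = _angle_at(p, k + 2)
    return Trajectory(traj.time_s.copy(), p[:, 0], p[:, 1], traj.fps)


def correct_jumps(traj: Trajectory, lookahead: int = 4, return_accepted: bool = False):
    """Bypass star-shaped jumps / non-mouse tracking points.

    From each accepted point, the nearest (Euclidean) of the subsequent
    ``lookahead`` points is taken as the next realistic location and the
    scan continues from there; skipped points are replaced by linear
    interpolation in time between accepted neighbors.  A trailing window
    shorter than ``lookahead`` shrinks accordingly.
    """
    n = len(traj)
    if n < 2:
        warnings.warn("fewer than 2 frames: jump correction skipped")
        out = Trajectory(traj.time_s.copy(), traj.x_cm.copy(), traj.y_cm.copy(), traj.fps)
        return (out, np.arange(n)) if return_accepted else out
    p = traj.points()
    accepted = [0]
    i = 0
    while i < n - 1:
        hi = min(i + lookahead, n - 1)
        window = p[i + 1 : hi + 1]
        d = np.linalg.norm(window - p[i], axis=1)
        j = i + 1 + int(np.argmin(d))
        accepted.append(j)
        i = j
    idx = np.asarray(accepted)
    x = np.interp(traj.time_s, traj.time_s[idx], traj.x_cm[idx])
    y = np.interp(traj.time_s, traj.time_s[idx], traj.y_cm[idx])
    out = Trajectory(traj.time_s.copy(), x, y, traj.fps)
    return (out, idx) if return_accepted else out


def smooth_trajectory(traj: Trajectory) -> Trajectory:
    """Smooth x and y independently by penalized least squares (GCV)."""
    return Trajectory(
        traj.time_s.copy(),
        smooth1d_gcv(traj.x_cm),
        smooth1d_gcv(traj.y_cm),
        traj.fps,
    )


def instant_speed(traj: Trajectory) -> np.ndarray:
    """Speed (cm/s) between neighboring locations; speed[0] copies speed[1]."""
    if len(traj) < 2:
        raise ValueError("need at least 2 frames for instant speed")
    dt = np.diff(traj.time_s)
    if np.any(dt <= 0):
        raise ValueError("zero or negative time lapse between frames")
    d = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
    sp = d / dt
    return np.concatenate([[sp[0]], sp])


def classify_frames(
    speeds: np.ndarray, speed_thresh: float = SPEED_THRESHOLD_CM_S
) -> np.ndarray:
    """Strict speed threshold: > thresh -> movement, otherwise immobility."""
    speeds = np.asarray(speeds, dtype=float)
    labels = np.full(speeds.shape, IMMOBILITY, dtype=np.int8)
    labels[speeds > speed_thresh] = MOVEMENT
    return labels


def _runs(labels: np.ndarray):
    """Yield (start, stop, value) for maximal constant runs (stop exclusive)."""
    n = labels.size
    if n == 0:
        return
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [n]])
    for a, b in zip(starts, stops):
        yield int(a), int(b), int(labels[a])


def despike_single_movement(labels: np.ndarray, n_flank: int = 10) -> np.ndarray:
    """Relabel isolated single movement frames flanked by immobility.

    A movement run of exactly one frame with at least ``n_flank``
    contiguous immobility frames immediately before and after it becomes
    immobility; longer movement runs are untouched.
    """
    labels = np.asarray(labels, dtype=np.int8)
    out = labels.copy()
    runs = list(_runs(labels))
    for r, (a, b, val) in enumerate(runs):
        if val != MOVEMENT or b - a != 1:
            continue
        if r == 0 or r == len(runs) - 1:
            continue
        pa, pb, pv = runs[r - 1]
        na, nb, nv = runs[r + 1]
        if pv == IMMOBILITY and nv == IMMOBILITY and (pb - pa) >= n_flank and (nb - na) >= n_flank:
            out[a] = IMMOBILITY
    return out


def apply_sleep_rule(
    labels: np.ndarray, fps: float, latency_s: float = SLEEP_LATENCY_S
) -> np.ndarray:
    """Relabel the tail of long immobility runs as sleep.

    Within each maximal immobility run strictly longer than
    ``latency_s``, frames whose run-relative time reaches ``latency_s``
    become sleep; shorter runs are untouched.
    """
    labels = np.asarray(labels, dtype=np.int8)
    out = labels.copy()
    min_frames = latency_s * fps
    for a, b, val in _runs(labels):
        if val != IMMOBILITY:
            continue
        if (b - a) / fps > latency_s:  # strictly longer than the latency
            first_sleep = a + int(np.ceil(min_frames - 1e-9))
            out[first_sleep:b] = SLEEP
    return out


def assign_sweeps(
    labels: np.ndarray,
    fps: float,
    sweep_s: float = SWEEP_S,
    dominance: float = DOMINANCE,
) -> SweepLabels:
    """Label 10-s sweeps by their dominant frame state.

    A state wins a sweep when its frame fraction is strictly greater
    than ``dominance``; otherwise the sweep is a mixed (transition)
    sweep.  Sweeps tile the session from t=0; a trailing partial sweep
    is dropped.
    """
    labels = np.asarray(labels, dtype=np.int8)
    frames_per_sweep = int(round(sweep_s * fps))
    if frames_per_sweep <= 0:
        raise ValueError("empty sweep: sweep_s * fps must be >= 1 frame")
    n_sweeps = labels.size // frames_per_sweep
    if n_sweeps == 0:
        raise ValueError("session shorter than one sweep")
    states = np.empty(n_sweeps, dtype=object)
    for s in range(n_sweeps):
        chunk = labels[s * frames_per_sweep : (s + 1) * frames_per_sweep]
        counts = np.bincount(chunk, minlength=3)
        best = int(np.argmax(counts))
        if counts[best] / frames_per_sweep > dominance:
            states[s] = _FRAME_TO_SWEEP[best]
        else:
            states[s] = "mixed"
    idx = np.arange(n_sweeps)
    return SweepLabels(idx, idx * sweep_s, states, sweep_s)


def stage_trajectory(
    traj: Trajectory,
    speed_thresh: float = SPEED_THRESHOLD_CM_S,
    latency_s: float = SLEEP_LATENCY_S,
    dominance: float = DOMINANCE,
    sweep_s: float = SWEEP_S,
    smooth: bool = True,
):
    """Run the full staging pipeline in its fixed order.

    Returns ``(cleaned_trajectory, FrameStates, SweepLabels)``.
    """
    cleaned = correct_sharp_turns(traj)
    cleaned = correct_jumps(cleaned)
    if smooth:
        cleaned = smooth_trajectory(cleaned)
    speeds = instant_speed(cleaned)
    labels = classify_frames(speeds, speed_thresh)
    labels = despike_single_movement(labels)
    labels = apply_sleep_rule(labels, traj.fps, latency_s)
    sweeps = assign_sweeps(labels, traj.fps, sweep_s, dominance)
    return cleaned, FrameStates(traj.time_s, labels, speeds), sweeps
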