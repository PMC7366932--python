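"""File formats: trajectory/event/sweep CSVs and EEG binary + JSON header.

The native EEG container is a raw float32 binary (channel-major) with a
JSON sidecar header ``{fs, n_channels, unit, gain, labels}``.  EDF files
are read through mne when available (install extra); derived signals are
never written back to EDF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecord
from .staging import FrameStates, SweepLabels, Trajectory, FRAME_STATE_NAMES

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_eeg_binary",
    "read_eeg",
    "write_frame_states_csv",
    "write_sweep_labels_csv",
    "read_sweep_labels_csv",
    "write_events_csv",
    "read_events_csv",
    "read_decisions_csv",
    "write_ground_truth",
]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_s": traj.time_s, "x_cm": traj.x_cm, "y_cm": traj.y_cm}).to_csv(
        path, index=False
    )


def read_trajectory_csv(path, fps: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 20.0
    return Trajectory(t, df["x_cm"].to_numpy(), df["y_cm"].to_numpy(), fps)


def write_eeg_binary(record: EEGRecord, path) -> None:
    """float32 channel-major binary + JSON sidecar (same stem, .json)."""
    path = Path(path)
    record.data.astype(np.float32).tofile(path)
    header = {
        "fs": record.fs,
        "n_channels": int(record.data.shape[0]),
        "unit": "mV",
        "gain": record.gain,
        "labels": list(record.channel_labels),
    }
    path.with_suffix(".json").write_text(json.dumps(header))


def read_eeg(path) -> EEGRecord:
    """Read raw binary + JSON header, or an EDF file (requires mne)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional, for EDF input only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e3  # mne works in V; store mV
        return EEGRecord(data, float(raw.info["sfreq"]), list(raw.ch_names))
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=np.float32).astype(float)
    n_ch = int(header["n_channels"])
    data = data.reshape(n_ch, -1)
    return EEGRecord(data, float(header["fs"]), list(header.get("labels", [])),
                     float(header.get("gain", 1.0)))


def write_frame_states_csv(frames: FrameStates, path) -> None:
    pd.DataFrame(
        {
            "time_s": frames.time_s,
            "state": [FRAME_STATE_NAMES[int(c)] for c in frames.labels],
            "speed_cm_s": frames.speed_cm_s,
        }
    ).to_csv(path, index=False)


def write_sweep_labels_csv(sweeps: SweepLabels, path) -> None:
    sweeps.to_frame().to_csv(path, index=False)


def read_sweep_labels_csv(path) -> SweepLabels:
    df = pd.read_csv(path)
    return SweepLabels(
        df["sweep_index"].to_numpy(),
        df["start_s"].to_numpy(),
        df["state"].to_numpy(dtype=object),
    )


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_decisions_csv(path) -> dict:
    """Rater decisions CSV ``event_id,accept`` -> {id: bool}."""
    df = pd.read_csv(path)
    return {int(r["event_id"]): bool(r["accept"]) for _, r in df.iterrows()}


def write_ground_truth(gt, out_dir) -> None:
    out_dir = Path(out_dir)
    gt.events.to_csv(out_dir / "true_events.csv", index=False)
    pd.DataFrame(
        {
            "sweep_index": np.arange(gt.sweep_states.size),
            "state": gt.sweep_states,
            "artifact": gt.artifact_flags(),
        }
    ).to_csv(out_dir / "true_sweeps.csv", index=False)
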