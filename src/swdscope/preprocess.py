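"""EEG normalization, 10-s sweep segmentation and artifact rejection.

Signals are stored gain-normalized in mV at the electrode.  Each channel
is cut into 10-s sweeps on the same grid as the behavioral sweeps; a
sweep whose summed 1-100 Hz Welch power exceeds 2e4 mV^2/Hz is excluded
from all further analysis, manual exclusions are unioned in, and a
channel qualifies for the database only if it has fewer than 60 noisy
sweeps (10 min).

The artifact-rule PSD is Welch with 1-s Hann segments and 50% overlap,
giving 1-Hz bins; "summed power" is the sum of the bin values over
1-100 Hz inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

__all__ = [
    "ARTIFACT_THRESHOLD_MV2HZ",
    "MAX_NOISY_SWEEPS",
    "EEGRecord",
    "SweepSet",
    "normalize_gain",
    "sweep_summed_power",
    "compute_sweep_powers",
    "flag_artifact_sweeps",
    "apply_manual_mask",
    "qualify_channel",
    "build_sweep_set",
]

ARTIFACT_THRESHOLD_MV2HZ = 2e4
MAX_NOISY_SWEEPS = 60
SWEEP_S = 10.0


@dataclass
class EEGRecord:
    """Continuous EEG in mV, one row per channel."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list = field(default_factory=lambda: ["right", "left"])
    gain: float = 1.0  # acquisition gain already divided out

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_sweeps(self) -> int:
        return self.n_samples // int(round(SWEEP_S * self.fs))

    def channel(self, i: int = 0) -> np.ndarray:
        return self.data[i]


@dataclass
class SweepSet:
    """Per-sweep summed 1-100 Hz power and artifact flags for one channel."""

    summed_power: np.ndarray  # mV^2/Hz per sweep
    artifact: np.ndarray  # bool per sweep
    fs: float
    sweep_s: float = SWEEP_S

    def __post_init__(self) -> None:
        self.summed_power = np.asarray(self.summed_power, dtype=float)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.summed_power.size != self.artifact.size:
            raise ValueError("flag array length must equal sweep count")

    def __len__(self) -> int:
        return int(self.artifact.size)

    def n_noisy(self) -> int:
        return int(self.artifact.sum())


def normalize_gain(raw: np.ndarray, gain: float) -> np.ndarray:
    """Divide out the acquisition gain, returning mV at the electrode."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return np.asarray(raw, dtype=float) / gain


def sweep_summed_power(
    sweep: np.ndarray, fs: float, lo_hz: float = 1.0, hi_hz: float = 100.0
) -> float:
    """Summed Welch power (mV^2/Hz over 1-Hz bins) across ``lo_hz..hi_hz``."""
    sweep = np.asarray(sweep, dtype=float)
    nper = int(round(fs))  # 1-s segments -> 1-Hz bins
    if sweep.size < int(round(SWEEP_S * fs)):
        raise ValueError("sweep shorter than 10 s")
    f, p = welch(sweep, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    mask = (f >= lo_hz) & (f <= hi_hz)
    return float(p[mask].sum())


def compute_sweep_powers(signal: np.ndarray, fs: float, sweep_s: float = SWEEP_S) -> np.ndarray:
    """Summed 1-100 Hz power for every full 10-s sweep of a channel."""
    signal = np.asarray(signal, dtype=float)
    spp = int(round(sweep_s * fs))
    n_sweeps = signal.size // spp
    return np.array(
        [sweep_summed_power(signal[s * spp : (s + 1) * spp], fs) for s in range(n_sweeps)]
    )


def flag_artifact_sweeps(
    summed_power: np.ndarray, threshold: float = ARTIFACT_THRESHOLD_MV2HZ
) -> np.ndarray:
    """Exclude sweeps with summed power strictly above the threshold."""
    return np.asarray(summed_power, dtype=float) > threshold


def apply_manual_mask(sweep_set: SweepSet, manual_indices) -> SweepSet:
    """Union manually cut noisy sweeps into the automatic exclusions."""
    manual_indices = np.asarray(list(manual_indices), dtype=int)
    flags = sweep_set.artifact.copy()
    if manual_indices.size:
        if manual_indices.min() < 0 or manual_indices.max() >= flags.size:
            raise IndexError("manual mask index out of range")
        flags[manual_indices] = True
    return SweepSet(sweep_set.summed_power.copy(), flags, sweep_set.fs, sweep_set.sweep_s)


def qualify_channel(sweep_set_or_flags, max_noisy: int = MAX_NOISY_SWEEPS) -> bool:
    """Channel qualifies iff its noisy-sweep count is strictly below 60."""
    if isinstance(sweep_set_or_flags, SweepSet):
        n_noisy = sweep_set_or_flags.n_noisy()
    else:
        n_noisy = int(np.asarray(sweep_set_or_flags).sum())
    return n_noisy < max_noisy


def build_sweep_set(
    signal: np.ndarray,
    fs: float,
    threshold: float = ARTIFACT_THRESHOLD_MV2HZ,
    manual_indices=(),
) -> SweepSet:
    """Segment, compute per-sweep power, and flag artifacts in one call."""
    powers = compute_sweep_powers(signal, fs)
    flags = flag_artifact_sweeps(powers, threshold)
    out = SweepSet(powers, flags, fs)
    if len(tuple(manual_indices)):
        out = apply_manual_mask(out, manual_indices)
    return out
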