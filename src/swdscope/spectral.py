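"""Welch power spectral density of merged SWDs and of the whole EEG.

All spectra are reduced to 1-Hz bins (bin b covers [b-0.5, b+0.5) Hz,
centers at integers 1..100).  The Welch estimator mirrors the classic
averaged-modified-periodogram defaults: Hamming window, 50% overlap,
segment length one eighth of the (10-s) analysis window.

Two normalizations are produced: absolute PSD (mV^2/Hz per bin) and
relative PSD, where each mouse's bins are divided by the summed
1-30 Hz power and multiplied by 5,000, so every relative spectrum sums
to exactly 5,000 over 1-30 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PSDResult",
    "bin_psd_1hz",
    "merged_swd_psd",
    "state_psd_absolute",
    "state_psd_relative",
    "psd_bin_tests",
]

SWEEP_S = 10.0
RELATIVE_SCALE = 5000.0
FMAX_HZ = 100
TEST_BAND = (1, 30)


@dataclass
class PSDResult:
    freq_hz: np.ndarray  # 1..100 bin centers
    power: np.ndarray  # per-bin power (mV^2/Hz for absolute)
    kind: str  # "absolute" or "relative"
    n_contributing_sweeps: int = 0

    def band(self, lo: int = 1, hi: int = 30) -> np.ndarray:
        mask = (self.freq_hz >= lo) & (self.freq_hz <= hi)
        return self.power[mask]


def _welch_default(x: np.ndarray, fs: float, ref_len: int | None = None):
    """Welch PSD with segment length = 1/8 of the 10-s analysis window.

    ``ref_len`` is the nominal analysis-window length in samples
    (default: the 10-s sweep), giving 1.25-s Hamming segments with 50%
    overlap regardless of how long the merged series happens to be;
    shorter inputs fall back to a single full-length segment.
    """
    x = np.asarray(x, dtype=float)
    ref = ref_len if ref_len is not None else int(round(SWEEP_S * fs))
    nper = max(8, int(round(ref / 8)))
    nper = min(nper, x.size)
    return welch(x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2)


def bin_psd_1hz(f: np.ndarray, p: np.ndarray, fmax: int = FMAX_HZ):
    """Average PSD values into 1-Hz bins centered at integers 1..fmax."""
    centers = np.arange(1, fmax + 1)
    power = np.zeros(centers.size)
    for i, b in enumerate(centers):
        mask = (f >= b - 0.5) & (f < b + 0.5)
        if mask.any():
            power[i] = float(p[mask].mean())
    return centers, power


def merged_swd_psd(
    signal: np.ndarray, fs: float, events: pd.DataFrame, states=None
) -> PSDResult:
    """PSD of all accepted SWDs merged into one time series.

    Accepted events (optionally restricted to the given behavioral
    states) are concatenated in time order; Welch runs over the merged
    series with 10-s-sweep-based segmentation, so a trailing partial
    window is handled by Welch's own overlap logic.
    """
    signal = np.asarray(signal, dtype=float)
    sel = events[events["accepted"]] if len(events) else events
    if states is not None and len(sel) and "state" in sel.columns:
        sel = sel[sel["state"].isin(states)]
    if len(sel) == 0:
        warnings.warn("no accepted SWD events: empty PSD")
        return PSDResult(np.arange(1, FMAX_HZ + 1), np.zeros(FMAX_HZ), "absolute", 0)
    sel = sel.sort_values("start_s")
    pieces = [
        signal[int(round(r["start_s"] * fs)) : int(round(r["end_s"] * fs))]
        for _, r in sel.iterrows()
    ]
    merged = np.concatenate([p for p in pieces if p.size])
    f, p = _welch_default(merged, fs, ref_len=int(round(SWEEP_S * fs)))
    centers, power = bin_psd_1hz(f, p)
    n_windows = max(1, merged.size // int(round(SWEEP_S * fs)))
    return PSDResult(centers, power, "absolute", n_windows)


def state_psd_absolute(
    signal: np.ndarray,
    fs: float,
    sweep_labels,
    artifact_flags: np.ndarray | None = None,
    state: str = "sleep",
) -> PSDResult | None:
    """Welch PSD per qualifying 10-s sweep of a state, averaged across sweeps."""
    signal = np.asarray(signal, dtype=float)
    states = np.asarray(sweep_labels.state, dtype=object)
    flags = (
        np.zeros(states.size, dtype=bool)
        if artifact_flags is None
        else np.asarray(artifact_flags, dtype=bool)[: states.size]
    )
    spp = int(round(SWEEP_S * fs))
    idx = np.flatnonzero((states == state) & ~flags)
    idx = idx[(idx + 1) * spp <= signal.size]
    if idx.size == 0:
        warnings.warn(f"no qualifying sweeps for state {state!r}")
        return None
    acc = None
    for s in idx:
        f, p = _welch_default(signal[s * spp : (s + 1) * spp], fs)
        acc = p if acc is None else acc + p
    centers, power = bin_psd_1hz(f, acc / idx.size)
    return PSDResult(centers, power, "absolute", int(idx.size))


def state_psd_relative(absolute: PSDResult) -> PSDResult:
    """Per-mouse relative PSD: bin / (summed 1-30 Hz power) * 5,000."""
    lo, hi = TEST_BAND
    mask = (absolute.freq_hz >= lo) & (absolute.freq_hz <= hi)
    total = float(absolute.power[mask].sum())
    if total <= 0:
        raise ValueError("zero total 1-30 Hz power: relative PSD undefined")
    return PSDResult(
        absolute.freq_hz.copy(),
        RELATIVE_SCALE * absolute.power / total,
        "relative",
        absolute.n_contributing_sweeps,
    )


def psd_bin_tests(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Independent-samples t-test per 1-Hz bin with BH-FDR across 1-30 Hz.

    ``group_a`` and ``group_b`` are (n_mice, 30) arrays of per-mouse PSD
    values over bins 1..30.  For a treatment-vs-saline contrast the
    control rows should pool both saline sessions.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 mice per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must cover the same frequency bins")
    t, p = ttest_ind(a, b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "freq_hz": np.arange(1, a.shape[1] + 1),
            "t": t,
            "p": p,
            "q": q,
            "significant": reject,
        }
    )
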