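"""Filtering, averaging and peak metrics for auditory brainstem responses.

The processing chain mirrors standard ABR practice: each sweep is
band-pass filtered 300-3000 Hz with a 4th-order Butterworth applied
forward-backward (zero phase, so latencies are preserved), sweeps are
averaged, and alternating positive peaks (P) and following troughs (N)
are located in the first 10 ms.  The detection threshold surrogate for
"reliably visible" is objective: the lowest stimulus level whose P1-N1
amplitude exceeds ``criterion_mult`` (default 4) times the no-stimulus
residual SD, confirmed by the next level also exceeding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from chrophys.datatypes import ABRSweepSet

BAND_HZ = (300.0, 3000.0)
PEAK_SEARCH_MS = (0.0, 10.0)
CRITERION_MULT = 4.0


@dataclass
class ABRMetrics:
    """Wave latencies and P-N amplitudes for one averaged waveform."""

    p_latencies: np.ndarray  # ms
    n_latencies: np.ndarray
    pn_amplitudes: np.ndarray  # µV
    waves_detected: int

    @property
    def p1_latency(self) -> float:
        return float(self.p_latencies[0]) if self.waves_detected else float("nan")

    @property
    def p1n1_amplitude(self) -> float:
        return float(self.pn_amplitudes[0]) if self.waves_detected else float("nan")


def _bandpass_sos(fs_khz: float):
    return butter(4, BAND_HZ, btype="bandpass", fs=fs_khz * 1000.0, output="sos")


def filter_and_average(sweeps: ABRSweepSet | np.ndarray, fs: float | None = None) -> np.ndarray:
    """Zero-phase band-pass each sweep, then average across sweeps.

    Accepts an :class:`ABRSweepSet` or a raw (n_sweeps x samples) array
    with ``fs`` in kHz.  Raises if the sweep is shorter than the filter
    warm-up (padding length of ``sosfiltfilt``).
    """
    if isinstance(sweeps, ABRSweepSet):
        arr, fs_khz = sweeps.sweeps, sweeps.fs
    else:
        arr = np.atleast_2d(np.asarray(sweeps, dtype=float))
        if fs is None:
            raise ValueError("fs (kHz) required for raw arrays")
        fs_khz = fs
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 sweeps to average")
    sos = _bandpass_sos(fs_khz)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if arr.shape[1] <= padlen:
        raise ValueError("sweeps shorter than the filter warm-up")
    filtered = sosfiltfilt(sos, arr, axis=1)
    return filtered.mean(axis=0)


def peak_metrics(
    waveform: np.ndarray,
    fs: float,
    n_waves: int = 5,
    noise_floor: float | None = None,
) -> ABRMetrics:
    """Locate up to ``n_waves`` P/N pairs in the 0-10 ms window.

    Positive peaks and their following troughs are taken earliest-first;
    amplitudes are P_i - N_i.  ``noise_floor`` (µV) suppresses peaks that
    are indistinguishable from residual noise; when None it is estimated
    as 3x the SD of the last quarter of the waveform (post-response).
    """
    waveform = np.asarray(waveform, dtype=float)
    n = min(int(PEAK_SEARCH_MS[1] * fs), waveform.size)
    seg = waveform[:n]
    if noise_floor is None:
        tail = waveform[int(0.75 * waveform.size) :]
        noise_floor = 3.0 * float(np.std(tail))
    peaks, _ = find_peaks(seg, prominence=max(noise_floor, 1e-12))
    p_lat, n_lat, pn = [], [], []
    last_n = 0
    for p in peaks:
        if p < last_n:
            continue
        rest = seg[p:]
        troughs, _ = find_peaks(-rest, prominence=max(noise_floor, 1e-12))
        if troughs.size == 0:
            t_idx = p + int(np.argmin(rest))
        else:
            t_idx = p + int(troughs[0])
        p_lat.append(p / fs)
        n_lat.append(t_idx / fs)
        pn.append(seg[p] - seg[t_idx])
        last_n = t_idx
        if len(p_lat) >= n_waves:
            break
    return ABRMetrics(
        p_latencies=np.asarray(p_lat),
        n_latencies=np.asarray(n_lat),
        pn_amplitudes=np.asarray(pn),
        waves_detected=len(p_lat),
    )


def abr_threshold(
    levels: np.ndarray,
    p1n1_amplitudes: np.ndarray,
    residual_sd: float,
    criterion_mult: float = CRITERION_MULT,
) -> float:
    """Objective ABR threshold over an ascending level series.

    Threshold is the lowest level whose P1-N1 amplitude exceeds
    ``criterion_mult x residual_sd`` with the next level also exceeding
    it (monotone confirmation; the top level confirms itself).  Returns
    NaN when no level qualifies.
    """
    levels = np.asarray(levels, dtype=float)
    amps = np.asarray(p1n1_amplitudes, dtype=float)
    if levels.size < 3:
        raise ValueError("need at least 3 stimulus levels")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be sorted ascending")
    crit = criterion_mult * residual_sd
    above = amps > crit
    for k in range(levels.size):
        if above[k] and (k == levels.size - 1 or above[k + 1]):
            return float(levels[k])
    return float("nan")


def rate_and_duration_curves(metrics: pd.DataFrame) -> pd.DataFrame:
    """Amplitude-vs-condition tables with per-animal peak normalization.

    ``metrics`` needs columns (animal, condition, p1n1_uv); the condition
    axis may be repetition rate (Hz) or pulse duration (ms).  Adds a
    ``p1n1_norm`` column (peak-normalized within animal) and returns the
    table sorted by condition.  The optimal condition per animal is the
    argmax of its curve.
    """
    req = {"animal", "condition", "p1n1_uv"}
    if not req.issubset(metrics.columns):
        raise ValueError(f"metrics must have columns {sorted(req)}")
    out = metrics.copy()
    out["p1n1_norm"] = out.groupby("animal")["p1n1_uv"].transform(
        lambda a: a / a.max() if a.max() > 0 else a
    )
    return out.sort_values(["animal", "condition"]).reset_index(drop=True)


def optimal_condition(metrics: pd.DataFrame) -> pd.Series:
    """Per-animal condition (e.g. pulse duration) maximizing P1-N1."""
    curves = rate_and_duration_curves(metrics)
    return curves.loc[curves.groupby("animal")["p1n1_uv"].idxmax()].set_index("animal")[
        "condition"
    ]
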