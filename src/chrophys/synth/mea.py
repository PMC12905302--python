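"""Synthetic multi-electrode inferior-colliculus recordings.

A linear array (default 50 µm pitch) records stimulus-locked multi-unit
activity.  Per trial and electrode, evoked spike counts are Poisson with
a sigmoidal rate-level mean scaled by a Gaussian spatial profile around
the stimulated tonotopic depth; spontaneous spikes run at the sigmoid
floor throughout the trial.  For pulse trains, spike phases within the
stimulus cycle are von Mises distributed, so the planted vector strength
is the Bessel ratio I1(kappa)/I0(kappa).  A common-mode stimulation
artefact (exponentially decaying transient, identical on every
electrode) is added at each light-pulse onset; global-mean subtraction
cancels it exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from chrophys.datatypes import MEARecording


@dataclass
class RateLevelSigmoid:
    """Spike rate (sp/s) as a sigmoid of stimulus intensity."""

    floor: float = 5.0
    ceiling: float = 200.0
    midpoint: float = 4.0
    slope: float = 1.0

    def rate(self, intensity: float) -> float:
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-(intensity - self.midpoint) * self.slope)
        )


@dataclass
class MEAParams:
    """Planted parameters for one synthetic multi-electrode recording."""

    n_electrodes: int = 32
    spacing_um: float = 50.0
    fs: float = 32.0  # kHz
    intensities: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    n_reps: int = 30
    rate_level: RateLevelSigmoid = field(default_factory=RateLevelSigmoid)
    best_depth_um: float = 800.0
    spatial_sigma_um: float = 150.0
    phase_kappa: float = 2.0
    phase_mu: float = np.pi / 2  # preferred phase within the cycle
    artefact_amp_uv: float = 0.0
    artefact_tau_ms: float = 0.5
    noise_sd_uv: float = 5.0
    spike_amp_uv: float = -50.0
    train: tuple[float, float, float] | None = None  # (duration ms, rate Hz, width ms)
    response_window: tuple[float, float] | None = None
    pre_ms: float = 110.0
    post_ms: float = 60.0
    include_blank: bool = True
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (ROC undefined otherwise)")
        if self.spike_amp_uv >= 0:
            raise ValueError("spike polarity is fixed negative")
        if self.fs <= 0 or self.n_electrodes < 1:
            raise ValueError("invalid geometry")
        if len(self.intensities) and np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly ascending")

    def window(self) -> tuple[float, float]:
        """Analysis window (ms, stimulus-relative) used to place evoked spikes."""
        if self.response_window is not None:
            return self.response_window
        return (0.0, 110.0) if self.train is not None else (2.0, 25.0)

    def planted_vs(self) -> float:
        """Expected vector strength of the von Mises phase distribution."""
        return float(i1(self.phase_kappa) / i0(self.phase_kappa))

    def spatial_factor(self, depth_um: np.ndarray) -> np.ndarray:
        return np.exp(
            -((depth_um - self.best_depth_um) ** 2) / (2.0 * self.spatial_sigma_um**2)
        )


def spike_kernel(fs: float, amp_uv: float) -> tuple[np.ndarray, int]:
    """Biphasic ~0.3 ms extracellular spike shape; returns (kernel, peak index).

    The negative trough sits at the returned index so that planted spike
    times coincide with the waveform trough.
    """
    t = np.arange(-0.15, 0.31, 1.0 / fs)
    k = -np.exp(-((t / 0.08) ** 2)) + 0.45 * np.exp(-(((t - 0.18) / 0.10) ** 2))
    k = k * (amp_uv / k.min())  # trough depth equals amp_uv (negative)
    peak = int(np.argmin(k))
    return k, peak


def _add_kernel(row: np.ndarray, idx: int, kernel: np.ndarray, peak: int) -> None:
    a = idx - peak
    b = a + kernel.size
    ka, kb = 0, kernel.size
    if a < 0:
        ka, a = -a, 0
    if b > row.size:
        kb -= b - row.size
        b = row.size
    if b > a:
        row[a:b] += kernel[ka:kb]


def gen_mea_recording(params: MEAParams, seed: int) -> MEARecording:
    """Generate a trial-structured recording with planted ground truth.

    Trials are laid out back-to-back, each ``pre_ms`` of silence followed
    by the stimulus and ``post_ms`` tail.  Blank (no-stimulus) trials come
    first, then ``n_reps`` trials per ascending intensity.  ``truth``
    carries per-channel spike times, per-trial evoked counts, the planted
    vector strength and the rate-level parameters.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fs = params.fs
    if params.train is not None:
        train_dur, pulse_rate, pulse_width = params.train
    else:
        train_dur, pulse_rate, pulse_width = 1.0, 0.0, 1.0

    trial_ms = params.pre_ms + max(train_dur, 1.0) + params.post_ms
    trial_n = int(round(trial_ms * fs))
    conditions: list[float] = []
    if params.include_blank:
        conditions += [np.nan] * params.n_reps
    for inten in params.intensities:
        conditions += [inten] * params.n_reps
    n_trials = len(conditions)
    n_samples = trial_n * n_trials

    depths = params.spacing_um * np.arange(params.n_electrodes)
    spatial = params.spatial_factor(depths)
    data = rng.normal(0.0, params.noise_sd_uv, size=(params.n_electrodes, n_samples)).astype(
        np.float32
    )

    kernel, kpeak = spike_kernel(fs, params.spike_amp_uv)
    kernel = kernel.astype(np.float32)

    win_lo, win_hi = params.window()
    win_s = (win_hi - win_lo) / 1000.0
    period_ms = 1000.0 / pulse_rate if pulse_rate > 0 else None

    # common-mode artefact template at each light-pulse onset
    art = None
    if params.artefact_amp_uv != 0.0:
        ta = np.arange(0.0, params.artefact_tau_ms * 8, 1.0 / fs)
        art = (params.artefact_amp_uv * np.exp(-ta / params.artefact_tau_ms)).astype(np.float32)

    events = []
    spike_times: list[list[float]] = [[] for _ in range(params.n_electrodes)]
    evoked_counts = np.zeros((params.n_electrodes, n_trials), dtype=int)
    rep_counter: dict[float, int] = {}

    for tr, inten in enumerate(conditions):
        t0 = tr * trial_ms
        stim_t = t0 + params.pre_ms
        key = -1.0 if np.isnan(inten) else float(inten)
        rep = rep_counter.get(key, 0)
        rep_counter[key] = rep + 1
        events.append(
            dict(
                time_ms=stim_t,
                kind="blank" if np.isnan(inten) else ("train" if params.train else "pulse"),
                intensity=np.nan if np.isnan(inten) else float(inten),
                rep=rep,
                train_dur_ms=train_dur if params.train else np.nan,
                pulse_rate_hz=pulse_rate if params.train else np.nan,
                pulse_width_ms=pulse_width,
            )
        )
        # stimulation artefact on every electrode at each pulse onset
        if art is not None and not np.isnan(inten):
            if params.train is not None and pulse_rate > 0:
                pulse_onsets = stim_t + np.arange(0.0, train_dur, period_ms)
            else:
                pulse_onsets = np.array([stim_t])
            for po in pulse_onsets:
                j = int(round(po * fs))
                seg = data[:, j : j + art.size]
                seg += art[: seg.shape[1]]

        for ch in range(params.n_electrodes):
            # spontaneous spikes over the whole trial
            n_spont = rng.poisson(params.rate_level.floor * trial_ms / 1000.0)
            tt = np.sort(rng.uniform(t0, t0 + trial_ms, n_spont))
            if not np.isnan(inten):
                extra = max(
                    0.0, params.rate_level.rate(inten) - params.rate_level.floor
                ) * win_s * spatial[ch]
                n_ev = rng.poisson(extra)
                evoked_counts[ch, tr] = n_ev
                if n_ev:
                    if params.train is not None and pulse_rate > 0:
                        n_cycles = int(round(train_dur / period_ms))
                        cyc = rng.integers(0, n_cycles, n_ev)
                        ph = rng.vonmises(params.phase_mu, params.phase_kappa, n_ev)
                        ph = np.mod(ph, 2 * np.pi)
                        ev = stim_t + cyc * period_ms + ph / (2 * np.pi) * period_ms
                    else:
                        ev = stim_t + rng.uniform(win_lo, win_hi, n_ev)
                    tt = np.sort(np.concatenate([tt, ev]))
            # enforce a refractory gap so planted trains are detectable
            if tt.size > 1:
                keep = np.concatenate([[True], np.diff(tt) > 1.0])
                tt = tt[keep]
            for s in tt:
                _add_kernel(data[ch], int(round(s * fs)), kernel, kpeak)
            spike_times[ch].extend(tt.tolist())

    events_df = pd.DataFrame(events)
    truth = {
        "spike_times": [np.array(s) for s in spike_times],
        "evoked_counts": evoked_counts,
        "planted_vs": params.planted_vs(),
        "phase_kappa": params.phase_kappa,
        "rate_level": params.rate_level,
        "spatial_factor": spatial,
        "response_window": (win_lo, win_hi),
        "trial_ms": trial_ms,
        "best_depth_um": params.best_depth_um,
    }
    return MEARecording(
        data=data,
        fs=fs,
        electrode_depths=depths,
        events=events_df,
        meta=dict(params.meta),
        truth=truth,
    )
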