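"""Kinetics and sensitivity metrics for single-cell photocurrent traces.

Implements the standard channelrhodopsin characterization battery:
monoexponential channel-closing fits (tau_off), biexponential decay
decomposition, desensitization ratio (I_stat/I_peak), current density
(|I_stat|/C), Hill fits of the intensity-response curve (EC50), per-pulse
spike probability, and a pulse-train fluctuation index.

Sign convention: inward currents are stored negative; ratios and
densities are reported on magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from chrophys.datatypes import CurrentTrace

# blank this long after light onset before searching the in-pulse peak,
# to skip the capacitive transient
PEAK_BLANK_MS = 0.2


@dataclass
class KineticsFit:
    """Result of a monoexponential decay fit."""

    tau_off: float
    amplitude: float
    baseline: float
    rmse: float
    n_points: int
    converged: bool


@dataclass
class BiexpFit:
    """Result of a biexponential decay fit, fast component first."""

    tau_fast: float
    tau_slow: float
    a_fast: float
    a_slow: float
    rmse: float
    collapsed: bool  # True when the two components were degenerate


@dataclass
class SensitivityCurve:
    """Hill fit of stationary photocurrent vs light intensity."""

    intensity: np.ndarray
    response: np.ndarray
    ec50: float
    hill: float
    i_max: float
    fitted: bool


def _window_slice(trace: CurrentTrace, window: tuple[float, float]) -> slice:
    lo = trace.sample_index(window[0])
    hi = trace.sample_index(window[1])
    return slice(max(lo, 0), min(hi + 1, trace.t.size))


def fit_monoexp_tau(trace: CurrentTrace, fit_window: tuple[float, float]) -> KineticsFit:
    """Least-squares monoexponential fit of the decaying photocurrent.

    Fits ``I(t) = A exp(-(t - t0)/tau) + b`` over ``fit_window`` (ms,
    absolute trace time), which must start at or after a pulse offset.
    The time constant is initialized from a log-linear regression on the
    baseline-subtracted decay, so the fit is deterministic.
    """
    if trace.pulse_offsets.size and fit_window[0] < trace.pulse_offsets.min() - 1e-9:
        raise ValueError("fit window must start at or after the pulse offset")
    sl = _window_slice(trace, fit_window)
    t = trace.t[sl] - trace.t[sl.start]
    y = trace.i[sl]
    if t.size < 10:
        raise ValueError("need at least 10 samples in the fit window")

    b0 = y[-max(3, t.size // 10) :].mean()
    a0 = y[0] - b0
    # log-linear initial tau on the decaying magnitude
    z = (y - b0) / a0 if a0 != 0 else np.ones_like(y)
    pos = z > 1e-3
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos], np.log(z[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    tau0 = float(np.clip(tau0, 1e-3, 10 * (t[-1] - t[0])))

    def model(tt, a, tau, b):
        return a * np.exp(-tt / tau) + b

    try:
        popt, _ = curve_fit(model, t, y, p0=[a0, tau0, b0], maxfev=10000)
        a, tau, b = popt
        resid = y - model(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        window_len = t[-1] - t[0]
        converged = bool(0 < tau <= 10 * window_len)
    except RuntimeError:
        a, tau, b, rmse, converged = np.nan, np.nan, np.nan, np.nan, False
    return KineticsFit(
        tau_off=float(tau),
        amplitude=float(a),
        baseline=float(b),
        rmse=rmse,
        n_points=int(t.size),
        converged=converged,
    )


def fit_biexp_fast(trace: CurrentTrace, fit_window: tuple[float, float]) -> BiexpFit:
    """Two-exponential decay fit, isolating the dominating fast component.

    Components are returned fast-first.  If the two time constants are
    degenerate (within 10% of each other) the fit collapses to a
    monoexponential and ``collapsed`` is set.
    """
    sl = _window_slice(trace, fit_window)
    t = trace.t[sl] - trace.t[sl.start]
    y = trace.i[sl]
    if t.size < 10:
        raise ValueError("need at least 10 samples in the fit window")
    span = t[-1] - t[0]
    a0 = y[0] - y[-1]

    def model(tt, a1, tau1, a2, tau2):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2) + y[-1]

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[0.8 * a0, span / 20.0, 0.2 * a0, span / 3.0],
            maxfev=20000,
        )
    except RuntimeError:
        popt = [np.nan] * 4
    a1, tau1, a2, tau2 = popt
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    collapsed = not np.isfinite(tau1) or abs(tau2 - tau1) <= 0.1 * max(tau1, tau2)
    if collapsed:
        mono = fit_monoexp_tau(trace, fit_window)
        return BiexpFit(
            tau_fast=mono.tau_off,
            tau_slow=mono.tau_off,
            a_fast=mono.amplitude,
            a_slow=0.0,
            rmse=mono.rmse,
            collapsed=True,
        )
    resid = y - model(t, a1, tau1, a2, tau2)
    return BiexpFit(
        tau_fast=float(tau1),
        tau_slow=float(tau2),
        a_fast=float(a1),
        a_slow=float(a2),
        rmse=float(np.sqrt(np.mean(resid**2))),
        collapsed=False,
    )


def desensitization_ratio(trace: CurrentTrace, pulse: int = 0) -> float:
    """I_stat / I_peak for a long (>= 100 ms) light pulse.

    I_stat is the mean over the last 10% of the pulse window, I_peak the
    extremum within the pulse after a 0.2 ms capacitive blank; both are
    measured relative to the pre-pulse baseline and reported on
    magnitudes.
    """
    on = trace.pulse_onsets[pulse]
    off = trace.pulse_offsets[pulse]
    if off - on < 100.0 - 1e-9:
        raise ValueError("desensitization ratio needs a pulse of >= 100 ms")
    pre = trace.i[: trace.sample_index(on)]
    baseline = np.median(pre) if pre.size else 0.0
    noise_sd = float(np.std(pre)) if pre.size > 1 else 0.0

    sl = _window_slice(trace, (on + PEAK_BLANK_MS, off))
    seg = trace.i[sl] - baseline
    i_peak = np.abs(seg).max()
    stat_sl = _window_slice(trace, (off - 0.1 * (off - on), off))
    i_stat = abs(float(np.mean(trace.i[stat_sl] - baseline)))
    if i_peak < 5 * noise_sd or i_peak == 0:
        raise ValueError("peak current indistinguishable from noise")
    return float(i_stat / i_peak)


def current_density(trace: CurrentTrace, pulse: int = 0) -> float:
    """Stationary current magnitude divided by cell capacitance (pA/pF)."""
    if trace.capacitance is None or trace.capacitance <= 0:
        raise ValueError("cell capacitance required for current density")
    on = trace.pulse_onsets[pulse]
    off = trace.pulse_offsets[pulse]
    pre = trace.i[: trace.sample_index(on)]
    baseline = np.median(pre) if pre.size else 0.0
    stat_sl = _window_slice(trace, (off - 0.1 * (off - on), off))
    i_stat = abs(float(np.mean(trace.i[stat_sl] - baseline)))
    return i_stat / trace.capacitance


def fit_ec50(intensity: np.ndarray, response: np.ndarray) -> SensitivityCurve:
    """Hill fit ``I(phi) = I_max phi^h / (phi^h + EC50^h)``.

    ``fitted`` is False when the plateau is not sampled (largest response
    below 90% of the fitted maximum) or when the fit fails.
    """
    intensity = np.asarray(intensity, dtype=float)
    response = np.abs(np.asarray(response, dtype=float))
    if intensity.size < 4:
        raise ValueError("need at least 4 intensity levels")
    if np.any(intensity <= 0) or np.any(np.diff(intensity) <= 0):
        raise ValueError("intensities must be positive and sorted ascending")

    def hill(phi, imax, ec50, h):
        return imax * phi**h / (phi**h + ec50**h)

    try:
        popt, _ = curve_fit(
            hill,
            intensity,
            response,
            p0=[response.max(), np.median(intensity), 1.0],
            bounds=([0, intensity.min() / 100, 0.1], [np.inf, intensity.max() * 100, 10]),
            maxfev=10000,
        )
        imax, ec50, h = popt
        fitted = bool(
            response.max() >= 0.9 * imax and intensity.min() <= ec50 <= intensity.max()
        )
    except RuntimeError:
        imax, ec50, h, fitted = np.nan, np.nan, np.nan, False
    return SensitivityCurve(
        intensity=intensity,
        response=response,
        ec50=float(ec50),
        hill=float(h),
        i_max=float(imax),
        fitted=fitted,
    )


def spike_probability(spike_flags: np.ndarray) -> float:
    """Fraction of light pulses that triggered a spike.

    ``spike_flags`` holds one boolean per pulse (spike within the
    response window after that pulse's onset).
    """
    flags = np.asarray(spike_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty pulse list")
    return float(flags.mean())


def spikes_to_flags(
    spike_times: np.ndarray, pulse_onsets: np.ndarray, window_ms: float = 10.0
) -> np.ndarray:
    """Mark each pulse whose response window contains at least one spike."""
    spike_times = np.asarray(spike_times, dtype=float)
    return np.array(
        [np.any((spike_times >= on) & (spike_times < on + window_ms)) for on in pulse_onsets]
    )


def pulse_train_fluctuation(trace: CurrentTrace, steady_tol: float = 0.05) -> tuple[float, bool]:
    """Peak-to-trough fluctuation index for a repetitive pulse train.

    Index = (steady-state per-cycle peak - preceding trough) / first-pulse
    peak, averaged over the last three cycles.  Approaches 1 when the
    current decays fully between pulses and 0 under continuous
    activation.  Returns ``(index, steady)`` where ``steady`` is False if
    the last three cycle peaks differ by more than ``steady_tol``.
    """
    onsets = trace.pulse_onsets
    if onsets.size < 5:
        raise ValueError("need at least 5 pulses")
    period = float(np.median(np.diff(onsets)))
    pre = trace.i[: trace.sample_index(onsets[0])]
    baseline = np.median(pre) if pre.size else 0.0

    peaks, troughs = [], []
    for on in onsets:
        sl = _window_slice(trace, (on, on + period))
        seg = np.abs(trace.i[sl.start : sl.stop - 1] - baseline)  # end-exclusive cycle
        peaks.append(seg.max())
        troughs.append(seg[int(0.5 * seg.size) :].min())
    peaks = np.asarray(peaks)
    troughs = np.asarray(troughs)
    last = peaks[-3:]
    steady = bool(np.ptp(last) <= steady_tol * max(last.mean(), 1e-12))
    index = float(np.mean(peaks[-3:] - troughs[-4:-1]) / peaks[0]) if peaks[0] > 0 else np.nan
    return index, steady
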