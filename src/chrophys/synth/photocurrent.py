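"""Synthetic channelrhodopsin photocurrent traces.

The model is phenomenological: on light onset the (inward, negative)
current steps to the peak and relaxes toward the stationary level with a
desensitization time constant; on light offset it decays
monoexponentially with the channel-closing constant tau_off.  With
``tau_on == 0`` activation is instantaneous, so the noise-free
post-pulse trace is exactly ``I(t_off) * exp(-dt / tau_off)`` and the
in-pulse extremum equals the planted peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chrophys.datatypes import CurrentTrace


@dataclass
class PhotocurrentParams:
    """Planted parameters for one photocurrent trace.

    Times in ms, currents in pA (magnitudes; the generated inward
    current is negative), sampling rate in kHz.
    """

    tau_on: float = 0.0
    tau_off: float = 5.0
    tau_des: float = 50.0
    i_peak: float = 100.0
    i_stat: float = 100.0
    pulse_onsets: tuple[float, ...] = (20.0,)
    pulse_width: float = 3.0
    duration: float = 100.0
    fs: float = 50.0
    noise_sd: float = 0.0
    capacitance: float = 26.33
    holding: float = -60.0
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.tau_off <= 0 or self.tau_des <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_on < 0:
            raise ValueError("tau_on must be non-negative")
        if self.i_stat > self.i_peak:
            raise ValueError("i_stat must not exceed i_peak")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        for on in self.pulse_onsets:
            if on < 0 or on + self.pulse_width > self.duration:
                raise ValueError("pulse window outside trace")


def _pulse_response(t: np.ndarray, on: float, off: float, p: PhotocurrentParams) -> np.ndarray:
    """Noise-free inward current (negative pA) for one light pulse."""
    i = np.zeros_like(t)
    during = (t >= on) & (t < off)
    td = t[during] - on
    amp = p.i_stat + (p.i_peak - p.i_stat) * np.exp(-td / p.tau_des)
    if p.tau_on > 0:
        amp = amp * (1.0 - np.exp(-td / p.tau_on))
    i[during] = -amp

    after = t >= off
    # value at the instant of light-off, continued as exp decay
    td_off = off - on
    amp_off = p.i_stat + (p.i_peak - p.i_stat) * np.exp(-td_off / p.tau_des)
    if p.tau_on > 0:
        amp_off = amp_off * (1.0 - np.exp(-td_off / p.tau_on))
    i[after] += -amp_off * np.exp(-(t[after] - off) / p.tau_off)
    return i


def gen_photocurrent(params: PhotocurrentParams, seed: int) -> CurrentTrace:
    """Generate one photocurrent trace with planted kinetics.

    Returns a :class:`CurrentTrace` whose ``truth`` dict records every
    planted parameter (tau_off, i_peak, i_stat, desensitization ratio).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    i = np.zeros(n)
    offs = []
    for on in params.pulse_onsets:
        off = on + params.pulse_width
        offs.append(off)
        i += _pulse_response(t, on, off, params)
    if params.noise_sd > 0:
        i = i + rng.normal(0.0, params.noise_sd, size=n)
    truth = {
        "tau_off": params.tau_off,
        "tau_des": params.tau_des,
        "i_peak": params.i_peak,
        "i_stat": params.i_stat,
        "desensitization_ratio": params.i_stat / params.i_peak,
        "noise_sd": params.noise_sd,
    }
    return CurrentTrace(
        t=t,
        i=i,
        fs=params.fs,
        pulse_onsets=np.asarray(params.pulse_onsets, dtype=float),
        pulse_offsets=np.asarray(offs, dtype=float),
        capacitance=params.capacitance,
        holding=params.holding,
        meta=dict(params.meta),
        truth=truth,
    )
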