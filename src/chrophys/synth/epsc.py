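"""Synthetic optically evoked EPSC trains (endbulb-of-Held style).

Each light pulse either succeeds (Bernoulli) and places a biexponential
inward current at a jittered synaptic delay, or fails.  The rise is
instantaneous so the per-event charge has the closed form
``A_fast * tau_fast + A_slow * tau_slow`` (pA*ms = fC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chrophys.datatypes import CurrentTrace


@dataclass
class EPSCTrainParams:
    """Planted parameters for a 50-pulse optogenetic stimulation train."""

    n_pulses: int = 50
    rate_hz: float = 10.0
    p_success: float | tuple[float, ...] = 1.0  # scalar or per-pulse
    delay_mean: float = 1.2  # ms
    delay_jitter: float = 0.0  # ms SD
    a_fast: float = 100.0  # pA
    a_slow: float = 20.0
    tau_fast: float = 0.3  # ms
    tau_slow: float = 3.0
    fs: float = 100.0  # kHz
    noise_sd: float = 0.0
    pre_ms: float = 10.0
    post_ms: float = 50.0
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        p = np.atleast_1d(np.asarray(self.p_success, dtype=float))
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_success must lie in [0, 1]")
        if not (0 < self.tau_fast < self.tau_slow):
            raise ValueError("need 0 < tau_fast < tau_slow")
        if self.n_pulses < 1 or self.rate_hz <= 0 or self.fs <= 0:
            raise ValueError("invalid train geometry")

    def per_pulse_p(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.p_success, dtype=float))
        if p.size == 1:
            return np.full(self.n_pulses, p[0])
        if p.size != self.n_pulses:
            raise ValueError("p_success length must match n_pulses")
        return p


def gen_epsc_train(params: EPSCTrainParams, seed: int) -> CurrentTrace:
    """Generate a stimulus train of EPSCs with planted successes/delays.

    ``truth`` holds the per-pulse success vector, the planted delays and
    the analytic per-event charge in pC.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    interval = 1000.0 / params.rate_hz
    onsets = params.pre_ms + interval * np.arange(params.n_pulses)
    duration = onsets[-1] + params.post_ms
    n = int(round(duration * params.fs))
    t = np.arange(n) / params.fs
    i = np.zeros(n)

    p = params.per_pulse_p()
    success = rng.random(params.n_pulses) < p
    delays = params.delay_mean + (
        rng.normal(0.0, params.delay_jitter, params.n_pulses)
        if params.delay_jitter > 0
        else np.zeros(params.n_pulses)
    )
    delays = np.clip(delays, 0.05, None)

    for k, on in enumerate(onsets):
        if not success[k]:
            continue
        t0 = on + delays[k]
        m = t >= t0
        td = t[m] - t0
        i[m] += -(
            params.a_fast * np.exp(-td / params.tau_fast)
            + params.a_slow * np.exp(-td / params.tau_slow)
        )
    if params.noise_sd > 0:
        i = i + rng.normal(0.0, params.noise_sd, size=n)

    charge_pc = (params.a_fast * params.tau_fast + params.a_slow * params.tau_slow) / 1000.0
    truth = {
        "success": success,
        "delays_ms": delays,
        "event_charge_pc": charge_pc,
        "tau_fast": params.tau_fast,
        "tau_slow": params.tau_slow,
        "a_fast": params.a_fast,
        "a_slow": params.a_slow,
        "probability": float(success.mean()),
    }
    return CurrentTrace(
        t=t,
        i=i,
        fs=params.fs,
        pulse_onsets=onsets,
        pulse_offsets=onsets + 1.0,  # 1 ms light pulses
        meta=dict(params.meta),
        truth=truth,
    )
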