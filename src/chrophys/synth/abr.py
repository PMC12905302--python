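"""Synthetic auditory brainstem response (ABR) sweep sets.

The stereotyped far-field waveform is a sum of five Gabor deflections
(waves I-V), each contributing a positive peak P_i followed by a
negative trough N_i within the first ~6 ms.  Wave amplitudes scale with
stimulus level through a sigmoid; latencies shift down slightly with
level, as in real ABRs.  The carrier (~1.2 kHz) and envelope width keep
the template inside the 300-3000 Hz analysis band so that zero-phase
band-pass filtering leaves the planted P1-N1 amplitude essentially
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chrophys.datatypes import ABRSweepSet


@dataclass
class ABRParams:
    """Planted parameters for one stimulus condition.

    ``p1n1_max`` is the saturated wave-I amplitude in µV; the planted
    amplitude at ``level`` follows a sigmoid with ``level_mid`` and
    ``level_slope``.  ``p1_latency`` is the planted wave-I peak time at
    saturation; latencies shift by ``latency_shift`` ms per (mid-level -
    level) unit below saturation.
    """

    p1n1_max: float = 14.95  # µV
    p1_latency: float = 0.61  # ms
    level: float = 10.0
    level_mid: float = 2.0
    level_slope: float = 1.0
    latency_shift: float = 0.0  # ms per level unit below mid
    n_sweeps: int = 1000
    fs: float = 50.0  # kHz
    window_ms: float = 20.0
    noise_sd: float = 0.0  # µV per sweep
    carrier_khz: float = 1.2  # retained for metadata; waves are DoG-shaped
    envelope_sd_ms: float = 0.3
    # relative amplitude and centre offset (ms) of waves I..V
    wave_amps: tuple[float, ...] = (1.0, 0.55, 0.7, 0.4, 0.3)
    wave_spacing_ms: float = 1.1
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.fs <= 0 or self.window_ms <= 0:
            raise ValueError("fs and window must be positive")
        n = self.fs * self.window_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window x fs must be an integer sample count")
        if any(a < 0 for a in self.wave_amps):
            raise ValueError("wave amplitudes must be non-negative")
        if self.n_sweeps < 1:
            raise ValueError("need at least one sweep")

    def amplitude_scale(self, level: float | None = None) -> float:
        """Sigmoidal level -> relative amplitude in (0, 1)."""
        lv = self.level if level is None else level
        return 1.0 / (1.0 + np.exp(-(lv - self.level_mid) * self.level_slope))


def _template(params: ABRParams, t: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Noise-free waveform plus its planted (P1 latency, P1-N1) truth."""
    scale = params.amplitude_scale()
    lat_shift = params.latency_shift * max(0.0, params.level_mid - params.level)
    # each wave is a derivative-of-Gaussian deflection: exactly one positive
    # peak (P, at c - sigma) followed by one trough (N, at c + sigma), no DC
    sigma = params.envelope_sd_ms
    c1 = params.p1_latency + lat_shift + sigma

    def synth_wave(tt: np.ndarray, c_first: float) -> np.ndarray:
        w = np.zeros_like(tt)
        for k, amp in enumerate(params.wave_amps):
            c = c_first + k * params.wave_spacing_ms
            u = (tt - c) / sigma
            w += -amp * u * np.exp(-0.5 * u**2)
        return w

    # measure the realized P1 on a fine grid and re-centre so the planted
    # P1 latency is exact despite wave overlap
    fine = np.arange(0.0, 10.0, 0.001)
    wf = synth_wave(fine, c1)
    ip = int(np.argmax(wf))
    c1 += params.p1_latency + lat_shift - fine[ip]
    wf = synth_wave(fine, c1)
    ip = int(np.argmax(wf))
    # N1 = first local trough after P1
    dw = np.diff(wf[ip:])
    turn = np.nonzero((dw[:-1] < 0) & (dw[1:] >= 0))[0]
    in_ = ip + (int(turn[0]) + 1 if turn.size else int(np.argmin(wf[ip:])))
    p1n1_raw = wf[ip] - wf[in_]
    target = params.p1n1_max * scale
    w = synth_wave(t, c1)
    if p1n1_raw > 0:
        w = w * (target / p1n1_raw)
    p1_lat = float(fine[ip])
    return w, p1_lat, float(target)


def gen_abr_sweeps(params: ABRParams, seed: int) -> ABRSweepSet:
    """Generate ``n_sweeps`` noisy repetitions of the level-scaled template."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.fs * params.window_ms))
    t = np.arange(n) / params.fs
    template, p1_lat, p1n1 = _template(params, t)
    sweeps = np.tile(template, (params.n_sweeps, 1))
    if params.noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, params.noise_sd, size=sweeps.shape)
    truth = {
        "template": template,
        "p1_latency_ms": p1_lat,
        "p1n1_uv": p1n1,
        "noise_sd": params.noise_sd,
        "level": params.level,
    }
    return ABRSweepSet(
        sweeps=sweeps,
        fs=params.fs,
        window_ms=params.window_ms,
        level=params.level,
        meta=dict(params.meta),
        truth=truth,
    )


def gen_abr_level_series(
    params: ABRParams, levels: list[float], seed: int
) -> list[ABRSweepSet]:
    """One sweep set per stimulus level (independent substreams)."""
    out = []
    ss = np.random.SeedSequence(seed).spawn(len(levels))
    for lv, sub in zip(levels, ss):
        p = ABRParams(**{**params.__dict__, "level": lv, "meta": dict(params.meta)})
        out.append(gen_abr_sweeps(p, int(sub.generate_state(1)[0] % (2**31))))
    return out
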