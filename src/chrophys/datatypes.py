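"""Core in-memory containers shared by all analysis stages.

Conventions
-----------
* time in milliseconds, sampling rates in kHz (samples per ms)
* membrane currents in pA, inward currents negative
* extracellular and far-field potentials in microvolts
* distances in micrometres

Each container is a plain dataclass; synthetic generators attach a
``truth`` dictionary holding the planted ground-truth parameters so that
downstream recovery can be scored without side channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class CurrentTrace:
    """A single-cell membrane-current recording with stimulus timing.

    Attributes
    ----------
    t : ndarray
        Uniform time grid in ms.
    i : ndarray
        Current in pA (inward negative), same length as ``t``.
    fs : float
        Sampling rate in kHz.
    pulse_onsets, pulse_offsets : ndarray
        Light-pulse windows in ms, inside the time grid.
    capacitance : float or None
        Cell capacitance in pF (needed for current density).
    holding : float or None
        Holding potential in mV.
    """

    t: np.ndarray
    i: np.ndarray
    fs: float
    pulse_onsets: np.ndarray
    pulse_offsets: np.ndarray
    capacitance: float | None = None
    holding: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        self.pulse_onsets = np.atleast_1d(np.asarray(self.pulse_onsets, dtype=float))
        self.pulse_offsets = np.atleast_1d(np.asarray(self.pulse_offsets, dtype=float))
        if self.t.shape != self.i.shape:
            raise ValueError("t and i must have the same shape")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("t must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def sample_index(self, t_ms: float) -> int:
        """Index of the grid point closest to ``t_ms``."""
        return int(round((t_ms - self.t[0]) * self.fs))


@dataclass
class MEARecording:
    """Multi-electrode extracellular voltage block with an event table.

    ``data`` is channels x samples in µV; ``events`` carries one row per
    stimulus presentation with columns (time_ms, kind, intensity, rep)
    and, for pulse trains, (train_dur_ms, pulse_rate_hz, pulse_width_ms).
    """

    data: np.ndarray
    fs: float
    electrode_depths: np.ndarray
    events: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.electrode_depths = np.asarray(self.electrode_depths, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.electrode_depths) != self.data.shape[0]:
            raise ValueError("one depth per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class SpikeTrain:
    """Per-channel spike times (ms) plus the detection context."""

    spike_times: list[np.ndarray]
    thresholds: np.ndarray
    noise_sd: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]


@dataclass
class ABRSweepSet:
    """Repeated far-field sweeps for one stimulus condition."""

    sweeps: np.ndarray  # n_sweeps x samples, µV
    fs: float  # kHz
    window_ms: float
    level: float
    rate_hz: float = 10.0
    pulse_width_ms: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        n = int(round(self.fs * self.window_ms))
        if self.sweeps.shape[1] != n:
            raise ValueError(
                f"window ({self.window_ms} ms at {self.fs} kHz) implies "
                f"{n} samples, got {self.sweeps.shape[1]}"
            )


@dataclass
class ImageStack:
    """Two-channel confocal stack: channels x z x y x x.

    Channel 0 is the context (cytoplasmic) marker, channel 1 the GFP
    (construct) channel.  ``pixel_size`` is the isotropic in-plane pixel
    pitch in µm/px, ``z_step`` the z spacing in µm.
    """

    data: np.ndarray
    pixel_size: float
    z_step: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError("data must be (2, z, y, x)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def context(self) -> np.ndarray:
        return self.data[0]

    @property
    def gfp(self) -> np.ndarray:
        return self.data[1]
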