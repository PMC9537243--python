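"""Uniformly sampled pulse-waveform container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Recognized channel kinds: capacitive pressure sensor, photoplethysmogram,
#: invasive arterial line, or anything else.
CHANNELS = ("cap", "ppg", "aline", "other")

#: Unit flags: raw sensor units (arbitrary) or calibrated pressure in mmHg.
UNITS = ("sensor", "mmHg")


@dataclass
class WaveformRecording:
    """A uniformly sampled single-channel pulse recording.

    Parameters
    ----------
    samples : ndarray
        Signal values, one per sample, all finite.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    channel : str
        One of :data:`CHANNELS`.
    units : str
        One of :data:`UNITS`; ``"sensor"`` means arbitrary units that
        require cuff calibration before they can be read as pressure.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel: str = "other"
    units: str = "sensor"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    def with_samples(self, samples: np.ndarray, **changes) -> "WaveformRecording":
        """Copy of this recording with new samples (and optional field changes)."""
        return replace(self, samples=np.asarray(samples, dtype=float), **changes)

    def copy(self) -> "WaveformRecording":
        return replace(self, samples=self.samples.copy())
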