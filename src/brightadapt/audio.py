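"""Core audio containers.

The unit of stimulation throughout the package is a short mono excerpt at
44.1 kHz, either music-like or speech-like.  Octave-band energy profiles
(0.125–16 kHz) are the summary statistic used both for corpus homogeneity
selection and for verifying the spectral-slope colorations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SAMPLE_RATE = 44100
"""All audio in this package is mono 44.1 kHz."""

OCTAVE_CENTERS_HZ = (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0)
"""Center frequencies of the octave analysis filterbank."""

RAMP_S = 0.050
"""Raised-cosine fade-in/out duration applied to every generated excerpt."""


@dataclass
class AudioExcerpt:
    """A mono waveform with domain and duration metadata.

    Parameters
    ----------
    samples
        Full-scale amplitudes in [-1, 1].
    rate
        Sampling rate in samples/s; must be 44100.
    domain
        ``"music"`` or ``"speech"``.
    duration_s
        Nominal duration in seconds; must match ``len(samples) / rate``
        within one sample period.
    excerpt_id
        Opaque unique label.
    speaker_id
        Opaque speaker label (speech only).
    """

    samples: np.ndarray
    rate: int
    domain: str
    duration_s: float
    excerpt_id: str
    speaker_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate != SAMPLE_RATE:
            raise ValueError(f"rate must be {SAMPLE_RATE}, got {self.rate}")
        if self.domain not in ("music", "speech"):
            raise ValueError(f"domain must be 'music' or 'speech', got {self.domain!r}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if abs(len(self.samples) / self.rate - self.duration_s) > 1.0 / self.rate:
            raise ValueError(
                f"duration_s={self.duration_s} inconsistent with "
                f"{len(self.samples)} samples at {self.rate} Hz"
            )
        peak = float(np.max(np.abs(self.samples)))
        if not np.isfinite(peak) or peak > 1.0 + 1e-9:
            raise ValueError(f"samples must be full-scale (|x| <= 1), peak={peak}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray) -> "AudioExcerpt":
        """Copy of this excerpt with new samples of the same length."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class OctaveBandProfile:
    """RMS energy level (dB) in each of the 8 octave bands 0.125–16 kHz."""

    levels_db: np.ndarray
    centers_hz: tuple[float, ...] = field(default=OCTAVE_CENTERS_HZ)

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels_db", np.asarray(self.levels_db, dtype=np.float64))
        if tuple(self.centers_hz) != OCTAVE_CENTERS_HZ:
            raise ValueError("octave centers must be 125 Hz ... 16 kHz, octave spaced")
        if self.levels_db.shape != (8,):
            raise ValueError("exactly 8 band levels required")
        if not np.all(np.isfinite(self.levels_db)):
            raise ValueError("band levels must be finite (silent band?)")


def raised_cosine_ramp(x: np.ndarray, rate: int = SAMPLE_RATE, ramp_s: float = RAMP_S) -> np.ndarray:
    """Apply a raised-cosine fade-in and fade-out of ``ramp_s`` seconds."""
    n_ramp = int(round(ramp_s * rate))
    if 2 * n_ramp > len(x):
        raise ValueError("signal shorter than twice the ramp")
    y = np.array(x, dtype=np.float64)
    # Half-cosine window rising from exactly 0 at the first sample.
    t = np.arange(n_ramp) / n_ramp
    env = 0.5 - 0.5 * np.cos(np.pi * t)
    y[:n_ramp] *= env
    y[-n_ramp:] *= env[::-1]
    return y


def peak_normalize(x: np.ndarray, peak_dbfs: float = -3.0) -> np.ndarray:
    """Scale ``x`` so its absolute peak sits at ``peak_dbfs`` dB full scale."""
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero signal")
    return x * (10.0 ** (peak_dbfs / 20.0) / peak)
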