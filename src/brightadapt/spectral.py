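"""Spectral coloration machinery.

Two coloration mechanisms are implemented:

* **Spectral-slope filtering** — the excerpt is split by a 5th-order
  Butterworth octave filterbank (centers 0.125–16 kHz), each band is
  weighted by ``slope × log2(center / 1 kHz)`` dB for centers between
  0.125 and 8 kHz (the gain is held at the boundary value outside that
  range), and the bands are summed back.  A slope of +1 dB/oct tilts the
  spectrum up, making the excerpt brighter.

* **Transfer-function morphing** — two acoustic transfer functions (a
  hear-through hearing device and the open ear) are inter-/extrapolated
  linearly in the log-magnitude and unwrapped-phase domains; morph level
  0 reproduces the device, 1 the open ear, and levels outside [0, 1]
  exaggerate their difference.

Band decomposition uses zero-phase (forward–backward) filtering by
default so the bands sum without phase cancellation; the squared
Butterworth magnitudes are power-complementary at the band edges, which
keeps the slope-0 analysis–synthesis chain flat within ±1 dB over
0.125–8 kHz.  Causal single-pass filtering is available via ``mode``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.fft import irfft, rfft, rfftfreq

from .audio import OCTAVE_CENTERS_HZ, SAMPLE_RATE, AudioExcerpt, OctaveBandProfile

logger = logging.getLogger(__name__)

MAX_ABS_SLOPE_DB_PER_OCT = 6.0


@dataclass(frozen=True)
class FilterSlopeSpec:
    """A linear-in-log-frequency gain tilt in dB per octave.

    The gain is 0 dB at ``pivot_hz`` and changes by ``slope_db_per_oct``
    per octave for band centers within the active region; centers outside
    it receive the boundary gain (the 16 kHz band gets the 8 kHz gain).
    """

    slope_db_per_oct: float
    pivot_hz: float = 1000.0
    active_band_lo_hz: float = 125.0
    active_band_hi_hz: float = 8000.0

    def band_gains_db(self, centers_hz=OCTAVE_CENTERS_HZ) -> np.ndarray:
        c = np.clip(np.asarray(centers_hz, dtype=float),
                    self.active_band_lo_hz, self.active_band_hi_hz)
        return self.slope_db_per_oct * np.log2(c / self.pivot_hz)


@lru_cache(maxsize=32)
def _octave_sos(center_hz: float, fs: int, order: int) -> np.ndarray:
    lo = center_hz / np.sqrt(2.0)
    hi = min(center_hz * np.sqrt(2.0), 0.999 * fs / 2.0)
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def octave_filterbank(x: np.ndarray, fs: int = SAMPLE_RATE, order: int = 5,
                      mode: str = "zero-phase") -> np.ndarray:
    """Decompose ``x`` into the 8 octave bands; returns shape (8, n)."""
    if mode not in ("zero-phase", "causal"):
        raise ValueError(f"mode must be 'zero-phase' or 'causal', got {mode!r}")
    bands = np.empty((len(OCTAVE_CENTERS_HZ), len(x)))
    for i, c in enumerate(OCTAVE_CENTERS_HZ):
        sos = _octave_sos(c, fs, order)
        if mode == "zero-phase":
            bands[i] = signal.sosfiltfilt(sos, x)
        else:
            bands[i] = signal.sosfilt(sos, x)
    return bands


def octave_band_levels(x: AudioExcerpt, mode: str = "zero-phase") -> OctaveBandProfile:
    """RMS energy level in dB per octave band (5th-order Butterworth bank).

    Raises
    ------
    ValueError
        If the excerpt is silent (log of zero energy).
    """
    if not np.any(x.samples):
        raise ValueError("cannot profile an all-zero excerpt")
    bands = octave_filterbank(x.samples, x.rate, mode=mode)
    rms = np.sqrt(np.mean(bands**2, axis=1))
    if np.any(rms == 0):
        raise ValueError("zero energy in at least one octave band")
    return OctaveBandProfile(levels_db=20.0 * np.log10(rms))


def apply_spectral_slope(x: AudioExcerpt, spec: FilterSlopeSpec,
                         mode: str = "zero-phase",
                         max_abs_slope: float = MAX_ABS_SLOPE_DB_PER_OCT) -> AudioExcerpt:
    """Re-colorate an excerpt with a spectral slope via the octave filterbank."""
    if abs(spec.slope_db_per_oct) > max_abs_slope:
        raise ValueError(
            f"|slope| = {abs(spec.slope_db_per_oct)} dB/oct exceeds the "
            f"permitted maximum of {max_abs_slope}"
        )
    bands = octave_filterbank(x.samples, x.rate, mode=mode)
    gains = 10.0 ** (spec.band_gains_db() / 20.0)
    return x.with_samples(gains @ bands)


class TransferFunction:
    """An LTI acoustic transfer function at 44.1 kHz.

    Holds an impulse response and, equivalently, its frequency response
    on a uniform ``n_fft``-point FFT grid (one-sided, ``n_fft // 2 + 1``
    complex bins).  Construct with :meth:`from_impulse_response` or
    :meth:`from_frequency_response`; the two representations round-trip
    exactly (up to FFT rounding, < 1e-9 relative).
    """

    def __init__(self, impulse_response: np.ndarray, n_fft: int,
                 rate: int = SAMPLE_RATE) -> None:
        ir = np.asarray(impulse_response, dtype=np.float64)
        if ir.ndim != 1 or ir.size == 0:
            raise ValueError("impulse response must be a non-empty 1-D array")
        if len(ir) > n_fft:
            raise ValueError("n_fft must be >= the impulse response length")
        self.impulse_response = ir
        self.n_fft = int(n_fft)
        self.rate = rate

    @classmethod
    def from_impulse_response(cls, ir: np.ndarray, n_fft: int | None = None,
                              rate: int = SAMPLE_RATE) -> "TransferFunction":
        ir = np.asarray(ir, dtype=np.float64)
        if n_fft is None:
            n_fft = 1 << int(np.ceil(np.log2(max(2 * len(ir), 2))))
        return cls(ir, n_fft, rate)

    @classmethod
    def from_frequency_response(cls, H: np.ndarray, n_fft: int,
                                rate: int = SAMPLE_RATE) -> "TransferFunction":
        H = np.asarray(H, dtype=np.complex128)
        if H.shape != (n_fft // 2 + 1,):
            raise ValueError(
                f"frequency response must have n_fft//2 + 1 = {n_fft // 2 + 1} "
                f"bins, got {H.shape}"
            )
        return cls(irfft(H, n=n_fft), n_fft, rate)

    @property
    def frequency_response(self) -> np.ndarray:
        return rfft(self.impulse_response, n=self.n_fft)

    @property
    def freqs_hz(self) -> np.ndarray:
        return rfftfreq(self.n_fft, d=1.0 / self.rate)

    def magnitude_db(self) -> np.ndarray:
        H = self.frequency_response
        if np.any(np.abs(H) == 0):
            raise ValueError("zero-magnitude bin; log magnitude undefined")
        return 20.0 * np.log10(np.abs(H))


@dataclass(frozen=True)
class MorphSpec:
    """Morph level m between the device (m=0) and open-ear (m=1) responses."""

    level: float

    def __post_init__(self) -> None:
        if not -0.5 - 1e-12 <= self.level <= 1.5 + 1e-12:
            raise ValueError(f"morph level must lie in [-0.5, 1.5], got {self.level}")


def morph_transfer_functions(tf_a: TransferFunction, tf_b: TransferFunction,
                             m: "MorphSpec | float") -> TransferFunction:
    """Inter-/extrapolate two transfer functions.

    The morph is linear in the log-magnitude and unwrapped-phase domains:
    ``|H_m|dB = (1-m)|H_a|dB + m|H_b|dB`` and likewise for the phase.
    ``m = 0`` reproduces ``tf_a`` (device) and ``m = 1`` reproduces
    ``tf_b`` (open ear) exactly.
    """
    level = m.level if isinstance(m, MorphSpec) else float(m)
    if tf_a.n_fft != tf_b.n_fft:
        raise ValueError(
            f"FFT grid mismatch: {tf_a.n_fft} vs {tf_b.n_fft}"
        )
    Ha, Hb = tf_a.frequency_response, tf_b.frequency_response
    for name, H in (("tf_a", Ha), ("tf_b", Hb)):
        mag = np.abs(H)
        zeros = np.flatnonzero(mag <= 1e-12 * mag.max())
        if zeros.size:
            raise ValueError(f"{name} has zero magnitude at bin {zeros[0]}")
    log_mag = (1.0 - level) * np.log(np.abs(Ha)) + level * np.log(np.abs(Hb))
    phase = ((1.0 - level) * np.unwrap(np.angle(Ha))
             + level * np.unwrap(np.angle(Hb)))
    Hm = np.exp(log_mag) * np.exp(1j * phase)
    return TransferFunction.from_frequency_response(Hm, tf_a.n_fft, tf_a.rate)


def apply_transfer_function(x: AudioExcerpt, tf: TransferFunction) -> AudioExcerpt:
    """Convolve an excerpt with a transfer function (output truncated to input length).

    The output is re-normalized only if the convolution would clip; the
    event is logged.
    """
    y = signal.fftconvolve(x.samples, tf.impulse_response)[: x.n_samples]
    peak = np.max(np.abs(y))
    if peak > 1.0:
        logger.info("apply_transfer_function: output peak %.3f > 1, re-normalizing", peak)
        y = y / peak
    return x.with_samples(y)
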