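"""Spectral-centroid brightness feature.

The model's only percept is the spectral centroid (SC) of an excerpt:
FFT magnitudes with a -90 dBFS floor are pooled into 128 bands spaced
uniformly on the ERB-number (Cam) scale, and the SC is the magnitude-
weighted mean of the band center frequencies,

    SC = sum_j f_j E_j / sum_j E_j .

Centers span 25 Hz – 20 kHz on the Glasberg–Moore ERB-number mapping
Cam(f) = 21.4 log10(1 + 0.00437 f).  Each FFT bin is assigned wholly to
the nearest band center on the Cam scale (rectangular grouping;
triangular weighting is available behind a flag).  dB full scale is
referenced so a full-scale sinusoid reads ~0 dBFS:
bin level = 20 log10(2 |X_k| / N).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq

from .audio import SAMPLE_RATE, AudioExcerpt

N_ERB_BANDS = 128
ERB_F_LO_HZ = 25.0
ERB_F_HI_HZ = 20000.0
MAGNITUDE_FLOOR_DBFS = -90.0


def hz_to_cam(f_hz):
    """Glasberg–Moore ERB-number (Cam) scale."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f_hz, dtype=float))


def cam_to_hz(cam):
    return (10.0 ** (np.asarray(cam, dtype=float) / 21.4) - 1.0) / 0.00437


@lru_cache(maxsize=1)
def erb_band_centers_hz(n_bands: int = N_ERB_BANDS) -> np.ndarray:
    """128 center frequencies uniformly spaced on the Cam scale."""
    cams = np.linspace(hz_to_cam(ERB_F_LO_HZ), hz_to_cam(ERB_F_HI_HZ), n_bands)
    return cam_to_hz(cams)


@dataclass(frozen=True)
class ERBSpectrum:
    """128-band ERB-grouped linear magnitude spectrum."""

    centers_hz: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers_hz", np.asarray(self.centers_hz, dtype=float))
        object.__setattr__(self, "magnitudes", np.asarray(self.magnitudes, dtype=float))
        if self.centers_hz.shape != (N_ERB_BANDS,) or self.magnitudes.shape != (N_ERB_BANDS,):
            raise ValueError(f"exactly {N_ERB_BANDS} bands required")
        if np.any(np.diff(self.centers_hz) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(self.magnitudes < 0):
            raise ValueError("band magnitudes must be non-negative")


@dataclass(frozen=True)
class SpectralCentroidValue:
    sc_hz: float


@lru_cache(maxsize=8)
def _bin_to_band(n_samples: int, rate: int, weighting: str):
    """Precomputed FFT-bin → ERB-band assignment for a given FFT length."""
    freqs = rfftfreq(n_samples, d=1.0 / rate)
    centers = erb_band_centers_hz()
    bin_cam = hz_to_cam(np.maximum(freqs, 1e-6))
    center_cam = hz_to_cam(centers)
    if weighting == "rectangular":
        mid = 0.5 * (center_cam[:-1] + center_cam[1:])
        idx = np.searchsorted(mid, bin_cam)
        return (idx,)
    if weighting == "triangular":
        # Fractional band position; each bin split between the two
        # flanking bands with weights linear on the Cam scale.
        pos = np.interp(bin_cam, center_cam, np.arange(N_ERB_BANDS))
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, N_ERB_BANDS - 1)
        w_hi = pos - lo
        return (lo, hi, w_hi)
    raise ValueError(f"weighting must be 'rectangular' or 'triangular', got {weighting!r}")


def erb_spectrum(x: AudioExcerpt, weighting: str = "rectangular") -> ERBSpectrum:
    """Single full-excerpt FFT, -90 dBFS floor, ERB grouping into 128 bands."""
    if x.n_samples == 0:
        raise ValueError("empty signal")
    mags = erb_magnitudes(x.samples, x.rate, weighting=weighting)
    return ERBSpectrum(centers_hz=erb_band_centers_hz(), magnitudes=mags)


def erb_magnitudes(samples: np.ndarray, rate: int = SAMPLE_RATE,
                   weighting: str = "rectangular") -> np.ndarray:
    """ERB-grouped magnitudes of a raw sample array (array-level workhorse)."""
    n = len(samples)
    mag = np.abs(rfft(samples))
    floor = (10.0 ** (MAGNITUDE_FLOOR_DBFS / 20.0)) * n / 2.0
    mag[mag < floor] = 0.0
    grouping = _bin_to_band(n, rate, weighting)
    if weighting == "rectangular":
        (idx,) = grouping
        return np.bincount(idx, weights=mag, minlength=N_ERB_BANDS)
    lo, hi, w_hi = grouping
    out = np.bincount(lo, weights=mag * (1.0 - w_hi), minlength=N_ERB_BANDS)
    out += np.bincount(hi, weights=mag * w_hi, minlength=N_ERB_BANDS)
    return out


def spectral_centroid(s: ERBSpectrum) -> SpectralCentroidValue:
    """Magnitude-weighted mean of the ERB band centers."""
    total = float(np.sum(s.magnitudes))
    if total <= 0:
        raise ValueError("all-zero spectrum: centroid undefined")
    return SpectralCentroidValue(sc_hz=float(np.dot(s.centers_hz, s.magnitudes) / total))


def sc_hz(x: AudioExcerpt) -> float:
    """Convenience: spectral centroid of an excerpt in Hz."""
    return spectral_centroid(erb_spectrum(x)).sc_hz


def slope_sc_table(corpus, slopes, mode: str = "zero-phase") -> dict:
    """SCs of every excerpt under every spectral slope.

    Returns a dict ``(excerpt_id, slope) -> sc_hz`` suitable for the
    decision model.  The octave-band decomposition is computed once per
    excerpt and re-weighted per slope, which is what makes large
    slope-grid simulations affordable.
    """
    from .spectral import FilterSlopeSpec, octave_filterbank

    gains = np.stack([
        10.0 ** (FilterSlopeSpec(s).band_gains_db() / 20.0) for s in slopes
    ])
    table = {}
    for e in corpus:
        bands = octave_filterbank(e.samples, e.rate, mode=mode)
        for s, g in zip(slopes, gains):
            mags = erb_magnitudes(g @ bands, e.rate)
            total = mags.sum()
            if total <= 0:
                raise ValueError(f"all-zero spectrum for {e.excerpt_id} at slope {s}")
            table[(e.excerpt_id, float(s))] = float(
                np.dot(erb_band_centers_hz(), mags) / total
            )
    return table


def morph_sc_table(corpus, tf_pair, morph_levels) -> dict:
    """SCs of every excerpt convolved with every morphed transfer function."""
    from .spectral import apply_transfer_function, morph_transfer_functions

    tfs = {float(m): morph_transfer_functions(tf_pair.device, tf_pair.open_ear, m)
           for m in morph_levels}
    return {
        (e.excerpt_id, m): sc_hz(apply_transfer_function(e, tf))
        for e in corpus for m, tf in tfs.items()
    }


def domain_median_sc(corpus, domain: str) -> float:
    """Median SC of the unprocessed excerpts of one stimulus domain
    (the fixed long-term reference of the LT decision model)."""
    scs = [sc_hz(e) for e in corpus if e.domain == domain]
    if not scs:
        raise ValueError(f"no excerpts of domain {domain!r}")
    return float(np.median(scs))


def batch_spectral_centroids(excerpts, condition=None) -> pd.DataFrame:
    """SCs for a sequence of excerpts, one row per excerpt.

    Returns a DataFrame with columns ``excerpt_id``, ``condition``,
    ``sc_hz`` — the serialization schema for batch feature extraction.
    """
    rows = [
        {"excerpt_id": e.excerpt_id, "condition": condition, "sc_hz": sc_hz(e)}
        for e in excerpts
    ]
    return pd.DataFrame(rows, columns=["excerpt_id", "condition", "sc_hz"])
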