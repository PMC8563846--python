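"""WAV and manifest serialization.

Audio is written as RIFF WAV, 32-bit float, mono, 44.1 kHz.  A corpus
manifest is a CSV with one row per excerpt (columns ``excerpt_id``,
``domain``, ``speaker_id``, ``duration_s``, ``path``).  Transfer
functions round-trip either as impulse-response WAVs or as two-column
magnitude/phase CSVs on a stated FFT grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audio import SAMPLE_RATE, AudioExcerpt
from .spectral import TransferFunction

MANIFEST_COLUMNS = ["excerpt_id", "domain", "speaker_id", "duration_s", "path"]


def write_wav(path, samples: np.ndarray, rate: int = SAMPLE_RATE) -> None:
    wavfile.write(path, rate, np.asarray(samples, dtype=np.float32))


def read_wav(path) -> tuple[int, np.ndarray]:
    rate, data = wavfile.read(path)
    return rate, np.asarray(data, dtype=np.float64)


def save_corpus(corpus: list[AudioExcerpt], out_dir) -> Path:
    """Write every excerpt as WAV plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in corpus:
        path = out_dir / f"{e.excerpt_id}.wav"
        write_wav(path, e.samples, e.rate)
        rows.append({
            "excerpt_id": e.excerpt_id, "domain": e.domain,
            "speaker_id": e.speaker_id or "", "duration_s": e.duration_s,
            "path": str(path),
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_corpus(manifest_path) -> list[AudioExcerpt]:
    df = pd.read_csv(manifest_path, keep_default_na=False)
    corpus = []
    for row in df.itertuples():
        rate, samples = read_wav(row.path)
        corpus.append(AudioExcerpt(
            samples, rate, row.domain, float(row.duration_s), row.excerpt_id,
            speaker_id=row.speaker_id or None,
        ))
    return corpus


def write_transfer_function_wav(path, tf: TransferFunction) -> None:
    write_wav(path, tf.impulse_response, tf.rate)


def read_transfer_function_wav(path, n_fft: int | None = None) -> TransferFunction:
    rate, ir = read_wav(path)
    return TransferFunction.from_impulse_response(ir, n_fft=n_fft, rate=rate)


def write_transfer_function_csv(path, tf: TransferFunction) -> None:
    """Magnitude (dB) / unwrapped phase (rad) per rfft bin, with n_fft recoverable."""
    H = tf.frequency_response
    pd.DataFrame({
        "freq_hz": tf.freqs_hz,
        "magnitude_db": 20.0 * np.log10(np.abs(H)),
        "phase_rad": np.unwrap(np.angle(H)),
    }).to_csv(path, index=False)


def read_transfer_function_csv(path, rate: int = SAMPLE_RATE) -> TransferFunction:
    df = pd.read_csv(path)
    n_fft = 2 * (len(df) - 1)
    H = 10.0 ** (df["magnitude_db"].to_numpy() / 20.0) * np.exp(1j * df["phase_rad"].to_numpy())
    return TransferFunction.from_frequency_response(H, n_fft, rate)
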