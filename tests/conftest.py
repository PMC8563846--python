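"""Shared fixtures.

Corpora and SC tables are expensive, so everything simulation-scale is
session scoped and generated once; unit tests use small corpora.
"""

from __future__ import annotations

import numpy as np
import pytest

from brightadapt.audio import SAMPLE_RATE, AudioExcerpt, peak_normalize, raised_cosine_ramp
from brightadapt.design import EXP1_SLOPES
from brightadapt.features import slope_sc_table
from brightadapt.stimuli import (
    generate_music_corpus,
    generate_speech_corpus,
    generate_transfer_function_pair,
)


def make_noise_excerpt(seed=0, duration_s=2.0, domain="music", color="white",
                       excerpt_id=None, ramp=True):
    """A raw noise excerpt for unit tests (white or pink)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * SAMPLE_RATE))
    x = rng.standard_normal(n)
    if color == "pink":
        from scipy.fft import irfft, rfft, rfftfreq

        X = rfft(x)
        f = rfftfreq(n, 1 / SAMPLE_RATE)
        X[1:] /= np.sqrt(f[1:])
        x = irfft(X, n=n)
    if ramp:
        x = raised_cosine_ramp(x)
    x = peak_normalize(x)
    return AudioExcerpt(x, SAMPLE_RATE, domain, duration_s,
                        excerpt_id or f"{color}-noise-{seed}")


@pytest.fixture(scope="session")
def white_noise_excerpt():
    return make_noise_excerpt(seed=1, duration_s=8.0)


@pytest.fixture(scope="session")
def pink_noise_excerpt():
    return make_noise_excerpt(seed=2, color="pink")


@pytest.fixture(scope="session")
def small_music_corpus():
    return generate_music_corpus(20, 2, seed=5)


@pytest.fixture(scope="session")
def tf_pair():
    return generate_transfer_function_pair(seed=1, contrast_db=6.0)


@pytest.fixture(scope="session")
def music_corpus_360():
    """Corpus large enough for Exp. 1/3/4 session designs."""
    return generate_music_corpus(360, 2, seed=100)


@pytest.fixture(scope="session")
def speech_corpus_360():
    """Speech corpus large enough for an Exp. 1 speech session."""
    return generate_speech_corpus(2, 90, seed=101)


@pytest.fixture(scope="session")
def exp2_corpus():
    """Music pools of 1/2/4/8 s for the interleaved adaptor design."""
    corpus = []
    for dur, n in ((1, 45), (2, 200), (4, 45), (8, 45)):
        corpus += generate_music_corpus(n, dur, seed=200 + dur)
    return corpus


@pytest.fixture(scope="session")
def exp3_slope_sc_table(music_corpus_360):
    """SCs of the 360-excerpt corpus at every slope of Exps. 1 and 3."""
    slopes = sorted({s + shift for s in EXP1_SLOPES for shift in (-1.0, 0.0, 1.0)})
    return slope_sc_table(music_corpus_360, slopes)
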