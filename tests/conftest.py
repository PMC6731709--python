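import numpy as np
import pandas as pd
import pytest

import speechlaws as sl


@pytest.fixture(scope="session")
def small_corpus():
    """20k-word corpus with the default statistical structure (rho=0.5)."""
    spec = sl.SyntheticSpec(
        vocabulary_size=800, n_tokens=20_000, n_speakers=6, seed=3
    )
    return sl.generate_corpus(spec)


@pytest.fixture(scope="session")
def big_corpus():
    """100k-word corpus for exponent-recovery checks."""
    spec = sl.SyntheticSpec(
        vocabulary_size=2000, n_tokens=100_000, n_speakers=10, seed=7
    )
    return sl.generate_corpus(spec)


@pytest.fixture(scope="session")
def independent_corpus():
    """Corpus with fully independent phoneme durations (rho=0, no type effect)."""
    spec = sl.SyntheticSpec(
        vocabulary_size=500,
        n_tokens=15_000,
        n_speakers=4,
        serial_corr=0.0,
        type_effect_sd=0.0,
        seed=11,
    )
    return sl.generate_corpus(spec)


def make_tokens(rows):
    """Token DataFrame from (speaker, level, label, onset, dur, wid, bid) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "speaker_id", "level", "label", "onset_s", "duration_s",
            "word_id", "bg_id",
        ],
    )
    for col in ("word_id", "bg_id"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df


@pytest.fixture
def tiny_corpus():
    """One BG, one word ('hi', 0.11 s), two phonemes of 0.05 s."""
    tokens = make_tokens(
        [
            ("s0", "word", "hi", 0.0, 0.11, 0, 0),
            ("s0", "phoneme", "h", 0.0, 0.05, 0, 0),
            ("s0", "phoneme", "iy", 0.05, 0.05, 0, 0),
        ]
    )
    return sl.SegmentedCorpus(tokens)
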