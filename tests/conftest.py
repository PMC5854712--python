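import numpy as np
import pytest

from songfractal.simulate import SongConfig, gen_song_corpus


@pytest.fixture(scope="session")
def clean_corpus():
    """Small zero-deviation corpus: every instance of a type is identical."""
    return gen_song_corpus(SongConfig(n_songs=5, notes_per_song=(6, 10),
                                      seed=101, deviation="none"))


@pytest.fixture(scope="session")
def mixed_corpus():
    """Small corpus with drift + motif + mild jitter deviations."""
    return gen_song_corpus(SongConfig(n_songs=6, notes_per_song=(6, 10),
                                      seed=202, deviation="mixed"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
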