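import numpy as np
import pytest
from hypothesis import settings

from slstream.lexicon import CONDITIONS, SYLLABARY_A, build_words
from slstream.sequence import StreamSpec, generate_sequence, place_chirps

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def words_by_condition():
    return {cond: build_words(SYLLABARY_A, cond) for cond in CONDITIONS}


@pytest.fixture(scope="session")
def streams(words_by_condition):
    """One chirped stream per condition at the study's stream spec."""
    out = {}
    for i, cond in enumerate(CONDITIONS):
        spec = StreamSpec(condition=cond, seed=100 + i)
        seq = generate_sequence(words_by_condition[cond], spec)
        out[cond] = place_chirps(seq, seed=200 + i)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
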