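import numpy as np
import pytest

from casq.encoder import ReferenceEncoder
from casq.fixtures import load_example_corpus, load_example_lexicon


@pytest.fixture(scope="session")
def encoder():
    return ReferenceEncoder(dim=64, seed=0)


@pytest.fixture(scope="session")
def example_corpus():
    """The two bundled brain-metabolism annotation trees."""
    return load_example_corpus()


@pytest.fixture(scope="session")
def example_lexicon():
    return load_example_lexicon()


class VecEncoder:
    """Test stub: fixed text->vector mapping, no hashing involved."""

    def __init__(self, mapping, dim):
        self._mapping = {k: np.asarray(v, dtype=np.float64) for k, v in mapping.items()}
        self.dim = dim

    def encode(self, text):
        return self._mapping[text].copy()


@pytest.fixture
def vec_encoder_factory():
    return VecEncoder
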