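import numpy as np
import pytest

from lexrsa.core import EmbeddingTable, Word, WordSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_words():
    return WordSet(
        (
            Word("shirt", "art", 12.0),
            Word("ship", "water", 30.0),
            Word("dress", "art", 8.0),
            Word("river", "water", 25.0),
            Word("paint", "art", 5.0),
            Word("lake", "water", 40.0),
        )
    )


@pytest.fixture
def small_emb(small_words, rng):
    vecs = rng.normal(size=(len(small_words), 4))
    return EmbeddingTable(tokens=small_words.tokens, vectors=vecs)
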