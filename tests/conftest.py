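import numpy as np
import pytest

from zjscreen import textmine
from zjscreen.syndata import CorpusSpec, PlateSpec, generate_corpus, generate_plate


@pytest.fixture(scope="session")
def default_corpus():
    """The default planted-association corpus (one planted pair, seed 0)."""
    return generate_corpus(CorpusSpec(seed=0))


@pytest.fixture(scope="session")
def trained_model(default_corpus):
    """Skip-gram model trained once on the default corpus; reused read-only."""
    return textmine.train_skipgram(default_corpus, textmine.SkipGramParams(seed=0))


@pytest.fixture()
def small_plate():
    spec = PlateSpec(
        candidates=(("cand_strong", 0.9, 0.9), ("cand_weak", 0.2, 0.2)),
        n_embryos=10,
        seed=42,
    )
    return generate_plate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
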