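import pytest

from simplerl.rewards import RewardScorer
from simplerl.synthetic_corpus import CorpusSpec, default_vocab, generate_corpus


@pytest.fixture(scope="session")
def vocab():
    return default_vocab()


@pytest.fixture(scope="session")
def lexicon(vocab):
    return vocab.lexicon()


@pytest.fixture(scope="session")
def scorer(lexicon):
    return RewardScorer(lexicon=lexicon)


@pytest.fixture(scope="session")
def small_corpus(vocab):
    """A 30-pair synthetic corpus for fast end-to-end tests."""
    return generate_corpus(vocab, CorpusSpec(n_pairs=30, seed=11))
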