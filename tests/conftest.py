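import pytest
from hypothesis import settings

from epenthesis_lab.fixtures import toy_lexicon_corpus
from epenthesis_lab.synthesis import SyntheticConfig, generate_corpus

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_corpus():
    """The five-lexeme homophony fixture, one single-word phrase per token."""
    return toy_lexicon_corpus()


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic corpus with ground truth (≈8k words)."""
    cfg = SyntheticConfig(seed=123, n_phrases=2000, n_word_types=800)
    return generate_corpus(cfg) + (cfg,)


@pytest.fixture(scope="session")
def default_synth():
    """The default study-condition corpus (≈10^5 words, deletion 0.10)."""
    cfg = SyntheticConfig()
    return generate_corpus(cfg) + (cfg,)
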