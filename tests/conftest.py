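import numpy as np
import pytest

from ldlex import LDLModel, LexiconSpec, generate_lexicon, generate_pseudowords


@pytest.fixture(scope="session")
def small_lexicon():
    """60-word synthetic lexicon with additive stem+exponent semantics."""
    return generate_lexicon(LexiconSpec(n_stems=60, semantic_dim=40,
                                        noise_sd=0.05, seed=7))


@pytest.fixture(scope="session")
def small_results(small_lexicon):
    """Fitted model on the small lexicon (orthographic comprehension cues)."""
    return LDLModel(small_lexicon, seed=7).fit()


@pytest.fixture(scope="session")
def small_pseudowords(small_lexicon):
    return generate_pseudowords(small_lexicon, n=25, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
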