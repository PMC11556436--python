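import numpy as np
import pytest

from syntrf import simulate as sim


@pytest.fixture(scope="session")
def toy_tree_text():
    return "(S (NP (Det the) (N train)) (VP (V arrived)))"


@pytest.fixture(scope="session")
def random_trees():
    """1,000 random toy-grammar trees (shared across property tests)."""
    _, trees = sim.gen_grammar_corpus(1000, seed=12345)
    return trees


@pytest.fixture(scope="session")
def toy_corpus():
    """A 50-sentence toy corpus for language-model tests."""
    sents, _ = sim.gen_grammar_corpus(50, seed=99)
    return sents


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
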