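import pytest

from phonosem import load_chardb, demo_chars_path
from phonosem.synthetic import SyntheticConfig, generate_chardb, generate_corpus


@pytest.fixture(scope="session")
def demo_db():
    """The shipped demonstration character table."""
    return load_chardb(demo_chars_path(), strict=True)


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic inventory + corpus shared across tests."""
    cfg = SyntheticConfig(n_chars=80, n_radicals=8, n_phonetic_pool=20,
                          n_sentences=60, seed=7)
    db, truth = generate_chardb(cfg)
    corpus = generate_corpus(cfg, db, seed=8)
    return cfg, db, truth, corpus
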