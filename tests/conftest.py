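import pytest

from cogexeval.corpus import CorpusConfig, generate_corpus


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-note corpus shared by read-only tests."""
    return generate_corpus(CorpusConfig(n_notes=200, seed=7))


@pytest.fixture(scope="session")
def big_bundle():
    """A corpus large enough for binomial-recovery checks (>=2000 gold
    MMSE+CDR tuples)."""
    bundle = generate_corpus(CorpusConfig(n_notes=1600, seed=13))
    n = sum(len(g.by_test("MMSE")) + len(g.by_test("CDR")) for g in bundle.gold)
    assert n >= 2000
    return bundle
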