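import pytest

from gramtriple import EngineConfig, build_indexes, load_ntriples
from gramtriple.fixtures import FixtureSpec, generate_corpus
from gramtriple.gram_index import GramIndex

# two-triple mnemonic corpus used throughout the worked examples
TWO_TRIPLE_NT = (
    '<Gpr64> <mnemonic> "GPR64_MOUSE" .\n'
    '<Ccdc80> <mnemonic> "CCD80_MOUSE" .\n'
)


@pytest.fixture(scope="session")
def fig_store():
    return load_ntriples(TWO_TRIPLE_NT)


@pytest.fixture(scope="session")
def go_store():
    """A mid-sized seeded GO-like corpus."""
    return load_ntriples(generate_corpus(FixtureSpec(seed=11, n_triples=1200)))


@pytest.fixture(scope="session")
def go_indexes(go_store):
    return build_indexes(go_store, EngineConfig())


@pytest.fixture(scope="session")
def small_store():
    return load_ntriples(generate_corpus(FixtureSpec(seed=5, n_triples=400)))


@pytest.fixture(scope="session")
def small_indexes(small_store):
    return build_indexes(small_store, EngineConfig())


def make_synthetic_index(keys, part="O", alpha=3, beta=3, postings=None):
    """A hand-assembled index with exactly the given keys (synthetic stand-in
    for a built index, for plan-shape tests)."""
    idx = GramIndex(part=part, alpha=alpha, beta=beta, sel_threshold=0.1)
    for k in sorted(keys):
        idx.entries[k] = list(postings.get(k, [(1, (0,))])) if postings else [(1, (0,))]
        idx.num_pages[k] = max(1, (len(idx.entries[k]) + 127) // 128)
    idx.height = 2
    return idx
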