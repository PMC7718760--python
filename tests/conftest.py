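import pytest

from litmine.synthetic_fixtures import (
    FixtureConfig,
    build_from_bundle,
    generate_bundle,
    toy_corpus_T1,
)


@pytest.fixture(scope="session")
def t1_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("t1")
    return toy_corpus_T1(out)


@pytest.fixture(scope="session")
def t1(t1_bundle):
    """(index, vocab, manifest) for the fixed 5-publication toy corpus."""
    paths, manifest = t1_bundle
    index, vocab = build_from_bundle(paths)
    return index, vocab, manifest


@pytest.fixture()
def make_bundle(tmp_path):
    """Factory: generate a seeded bundle and build its index."""

    def _make(seed=0, **kw):
        config = FixtureConfig(seed=seed, **kw)
        paths, manifest = generate_bundle(config, tmp_path / f"bundle{seed}")
        index, vocab = build_from_bundle(paths)
        return paths, manifest, index, vocab

    return _make
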