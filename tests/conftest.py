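import pytest

from foodner import FixtureSpec, default_lexicon, generate


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def fixture_bundle():
    """Six deterministic synthetic recipes with their gold corpus."""
    return generate(FixtureSpec(seed=7, n_recipes=6))


@pytest.fixture(scope="session")
def gold_corpus(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def recipes(fixture_bundle):
    return fixture_bundle[0]
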