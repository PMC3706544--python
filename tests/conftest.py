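import pytest

from melagl import assemble_test_set, build_feature_tables, fixture_grammar


@pytest.fixture(scope="session")
def grammar():
    return fixture_grammar()


@pytest.fixture(scope="session")
def alphabet(grammar):
    return grammar.alphabet


@pytest.fixture(scope="session")
def stim_set(grammar):
    """Default 66-item test set (seed 1)."""
    return assemble_test_set(grammar, seed=1)


@pytest.fixture(scope="session")
def feature_tables(stim_set):
    """ACS feature tables (pitch + interval views), computed once."""
    return build_feature_tables(stim_set)


@pytest.fixture(scope="session")
def test_melodies(stim_set):
    return [s.pitches for s in stim_set.test_set]
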