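import pytest

from limoscreen import default_ruleset, enumerate_candidates, parse_formula
from limoscreen.io import load_fixture, table2_features


@pytest.fixture(scope="session")
def library():
    """Default limonene candidate library."""
    return enumerate_candidates(parse_formula("C10H16"), "limonene",
                                default_ruleset())


@pytest.fixture(scope="session")
def fixture_df():
    return load_fixture("table2_features")


@pytest.fixture(scope="session")
def urine_features():
    return table2_features("urine")


@pytest.fixture(scope="session")
def liver_features():
    return table2_features("liver")
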