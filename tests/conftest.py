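import pytest

from lcofrag import MatchParams, SearchSpace, enumerate_structures


@pytest.fixture(scope="session")
def default_space() -> SearchSpace:
    return SearchSpace()


@pytest.fixture(scope="session")
def default_structures(default_space):
    """Every structure in the default search space (320 candidates)."""
    return enumerate_structures(default_space)


@pytest.fixture
def nominal_params() -> MatchParams:
    return MatchParams(nominal_mode=True)
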