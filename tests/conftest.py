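import pytest

from t2dcea import canonical_life_table, canonical_parameter_set


@pytest.fixture(scope="session")
def ps():
    """Canonical seed-0 synthetic parameter registry."""
    return canonical_parameter_set()


@pytest.fixture(scope="session")
def lt():
    """Canonical Gompertz life table (ages 40..110)."""
    return canonical_life_table()
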