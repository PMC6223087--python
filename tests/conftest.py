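import pytest

from deblend.synthetic import standard_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The fixed-seed synthetic bundles shared across the suite."""
    return standard_fixtures()


@pytest.fixture(scope="session")
def overdet(fixtures):
    return fixtures["overdet"]


@pytest.fixture(scope="session")
def overdet_noiseless(fixtures):
    return fixtures["overdet_noiseless"]


@pytest.fixture(scope="session")
def underdet(fixtures):
    return fixtures["underdet"]
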