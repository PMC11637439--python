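import pytest

from xpakit import fixtures, seqtools
from xpakit.variants import fixture_variants


@pytest.fixture(scope="session")
def cohort():
    return fixtures.fixture_cohort()


@pytest.fixture(scope="session")
def variant_table():
    return fixture_variants()


@pytest.fixture(scope="session")
def donor_matrix():
    return seqtools.default_donor_matrix()
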