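import pytest

from recinorm import ErrorRates, catalog_lookup
from recinorm.fixtures import generate_fixtures

LEADING_EIGHT = [f"L{i}" for i in range(1, 9)]
SECONDARY_SIXTEEN = [f"S{i}" for i in range(1, 17)]


@pytest.fixture(scope="session")
def mu3() -> ErrorRates:
    """The default working error rates mu_e = mu_a1 = mu_a2 = 1e-3."""
    return ErrorRates.uniform(1e-3)


@pytest.fixture(scope="session")
def random_stochastic_norms():
    return generate_fixtures(25, seed=20230720, kind="stochastic")


@pytest.fixture(scope="session")
def random_deterministic_norms():
    return generate_fixtures(25, seed=20230721, kind="deterministic")


@pytest.fixture(scope="session", params=LEADING_EIGHT + SECONDARY_SIXTEEN)
def donor_only_cess_norm(request):
    """Each of the 24 classical donor-only cooperative norms."""
    return catalog_lookup(request.param)
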