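import pytest

from hystcea import (
    load_default_age_distribution,
    load_default_lifetable,
    load_default_parameter_table,
    resolve_base_case,
)


@pytest.fixture(scope="session")
def specs():
    return load_default_parameter_table()


@pytest.fixture(scope="session")
def base_params(specs):
    return resolve_base_case(specs)


@pytest.fixture(scope="session")
def age_dist():
    return load_default_age_distribution()


@pytest.fixture(scope="session")
def lifetable():
    return load_default_lifetable()
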