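import pytest

from fametrics import (
    default_melting_table,
    load_fungal_profiles,
    load_printed_reference,
)


@pytest.fixture(scope="session")
def fungal_profiles():
    return load_fungal_profiles()


@pytest.fixture(scope="session")
def printed_reference():
    return load_printed_reference()


@pytest.fixture(scope="session")
def melting_table():
    return default_melting_table()
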