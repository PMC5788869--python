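import pytest

from mirnovo.fixtures import reference_fixtures
from mirnovo.fold import load_energy_model


@pytest.fixture(scope="session")
def model():
    return load_energy_model()


@pytest.fixture(scope="session")
def fx():
    return reference_fixtures()
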