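import pytest

from liga import build_fixture
from liga.synth import default_design


@pytest.fixture(scope="session")
def liga6x5():
    return build_fixture("liga6x5", seed=7)


@pytest.fixture(scope="session")
def design():
    return default_design()
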