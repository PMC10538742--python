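import pytest

from greycast import AnalysisConfig, michigan_roundabouts


@pytest.fixture(scope="session")
def michigan():
    return michigan_roundabouts()


@pytest.fixture()
def config():
    return AnalysisConfig()
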