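import pytest

from jdint import AnalysisConfig, builtin_references


@pytest.fixture(scope="session")
def refs():
    return builtin_references()


@pytest.fixture(scope="session")
def wt(refs):
    return refs["wt_atxn3"]


@pytest.fixture(scope="session")
def exp(refs):
    return refs["exp_atxn3"]


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()
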