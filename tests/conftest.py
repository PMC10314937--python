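import pytest

from btexrisk import load_analytes, load_study_strata


@pytest.fixture(scope="session")
def analytes():
    return load_analytes()


@pytest.fixture(scope="session")
def strata():
    return load_study_strata()
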