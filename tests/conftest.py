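import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

SPACER = "GACCTTGCATCAGTACGGAT"


@pytest.fixture(scope="session")
def guide():
    from cutscan.ttiss import GuideSpec
    return GuideSpec("guide1", SPACER)


@pytest.fixture(scope="session")
def spacer():
    return SPACER
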