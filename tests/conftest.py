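import pytest
from hypothesis import settings

from bindm.io import load_fixtures

settings.register_profile("suite", derandomize=True, max_examples=75)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fx():
    """Packaged published summary tables."""
    return load_fixtures()
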