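import pytest

from plainlens.lexicons import default_bundle


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()
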