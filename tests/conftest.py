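import pytest

from sippk import fluconazole, siponimod


@pytest.fixture(scope="session")
def sip():
    return siponimod()


@pytest.fixture(scope="session")
def flu():
    return fluconazole()
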