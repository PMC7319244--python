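import pytest

from helpers import make_panel, uniform_mlg


@pytest.fixture
def panel12():
    return make_panel(12)


@pytest.fixture
def base_mlg(panel12):
    return uniform_mlg(panel12)
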