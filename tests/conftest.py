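import pytest

from pkmz_switch import ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Default (published) parameter set."""
    return ModelParams()
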