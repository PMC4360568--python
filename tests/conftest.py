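import pytest

from genload import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    """M=7, N=1 and the standard genome constants."""
    return ModelParams()
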