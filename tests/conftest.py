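import numpy as np
import pytest

from driftpulse import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def study_config():
    """The canonical three-pool configuration (0/2677, 4/95, 124/957)."""
    return ModelConfig.paper_defaults()
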