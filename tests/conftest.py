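import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from otoquant.synthetic_data import SimulationConfig


@pytest.fixture
def clean_config():
    """Noiseless configuration: ground truth must be recovered exactly."""
    return SimulationConfig(seed=11, noise_sd=0.0)


@pytest.fixture
def noisy_config():
    """Moderate Gaussian noise, ~5% of the default focus contrast."""
    return SimulationConfig(seed=11, noise_sd=5.0)
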