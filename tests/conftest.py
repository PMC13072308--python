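import sys
from pathlib import Path

import pytest

# make the sibling oracles module importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))

from phagekit.simulate import SimulationConfig


@pytest.fixture
def noiseless():
    """Config with noise disabled, for closed-form expectation checks."""
    return SimulationConfig(seed=0, noise_sd=0.0)


@pytest.fixture
def noisy():
    """Default assay noise at a fixed seed."""
    return SimulationConfig(seed=20240917, noise_sd=0.05)
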