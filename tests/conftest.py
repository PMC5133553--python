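import numpy as np
import pytest

from strainmorph import AnalyticDeformation, default_grid, sample_field


@pytest.fixture
def grid16():
    return default_grid(16, spacing=2.0)


@pytest.fixture
def grid8():
    return default_grid(8, spacing=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def shear_field(grid16):
    """Simple shear gamma=0.2 in the xy plane, with its oracle maps."""
    return sample_field(AnalyticDeformation.simple_shear(0.2, "xy"), grid16)
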