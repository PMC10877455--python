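import numpy as np
import pytest

from depstrat.core import VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid8():
    """Small full-mask grid, 4 mm isotropic."""
    return VolumeGrid.full((8, 8, 8))


@pytest.fixture
def grid5():
    """Tiny full-mask grid for brute-force oracles."""
    return VolumeGrid.full((5, 5, 5))
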