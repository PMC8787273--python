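import numpy as np
import pytest

from spindlemorph import morphometry as morph
from spindlemorph import synthetic as syn


@pytest.fixture(scope="session")
def control_field():
    """One default-noise control field of view (1024 px, seed 11)."""
    return syn.generate_field(syn.CONTROL, seed=11)


@pytest.fixture(scope="session")
def noiseless_control_field():
    return syn.generate_field(syn.CONTROL, seed=11,
                              settings=syn.NOISELESS_RENDER)


@pytest.fixture(scope="session")
def thresholds():
    return morph.PUBLISHED_THRESHOLDS


def rectangle_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m
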