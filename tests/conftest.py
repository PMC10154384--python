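import numpy as np
import pytest

from mechassay import pillars, synth


@pytest.fixture
def spec() -> pillars.PillarArraySpec:
    return pillars.PillarArraySpec()


@pytest.fixture
def cell_mask() -> np.ndarray:
    return synth.ellipse_mask((128, 128), (64, 64), (42, 36))
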