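import numpy as np
import pytest

from fluctmap import RoiMask
from fluctmap.synthetic import preset_spec, simulate


@pytest.fixture(scope="session")
def roi96():
    """Canonical analysis ROI for the 96x96 fixture clips."""
    return RoiMask.from_rect(16, 16, 80, 80, (96, 96))


@pytest.fixture(scope="session")
def static_clip():
    loop, truth = simulate(preset_spec("static", seed=11))
    return loop, truth


@pytest.fixture(scope="session")
def flutter_clip():
    loop, truth = simulate(preset_spec("flutter", seed=11))
    return loop, truth


@pytest.fixture(scope="session")
def pulsation_clip():
    loop, truth = simulate(preset_spec("pulsation", seed=11))
    return loop, truth
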