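import numpy as np
import pytest

from thermaseg import phantom as ph


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Healthy symmetric phantom: (spec, thermogram, thermal, truth)."""
    spec = ph.PhantomSpec.default(seed=7)
    return (spec, *ph.generate(spec))


@pytest.fixture(scope="session")
def lesion_phantom():
    """Phantom with a 2 °C warm lesion in the patient's right breast."""
    spec = ph.PhantomSpec.default(seed=11, lesion_side="right", lesion_delta_t=2.0)
    return (spec, *ph.generate(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
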