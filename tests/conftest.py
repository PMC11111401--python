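import numpy as np
import pytest

from paleoresil.calcurves import synth_curve


@pytest.fixture(scope="session")
def identity_curve():
    """Identity calibration curve (c14_age(t) = t) with zero curve error."""
    return synth_curve((8000, 0), sigma=0.0)


@pytest.fixture(scope="session")
def noisy_curve():
    """Identity-mean curve with a constant 5-yr curve uncertainty."""
    return synth_curve((8000, 0), sigma=5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)
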