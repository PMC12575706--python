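import numpy as np
import pytest
from hypothesis import settings

from nacre.tmm import DEFAULT_WAVELENGTHS, Spectrum

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wl():
    """Default visible grid, 380-780 nm at 1 nm."""
    return DEFAULT_WAVELENGTHS


def gaussian_band(center, sigma, height=1.0, baseline=0.0, wl=DEFAULT_WAVELENGTHS):
    """Synthetic Gaussian reflection band on a constant baseline."""
    v = baseline + height * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return Spectrum(wl, v)
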