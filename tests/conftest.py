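import numpy as np
import pytest

from specbind.spectra import Spectrum


def gaussian_spectrum(center, sigma=8.0, amplitude=100.0, lo=None, hi=None, step=1.0,
                      kind="emission"):
    """Gaussian band sampled on a uniform grid; the shared peak fixture."""
    lo = center - 6 * sigma if lo is None else lo
    hi = center + 6 * sigma if hi is None else hi
    axis = np.arange(lo, hi + 1e-9, step)
    return Spectrum(axis, amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2), kind)


@pytest.fixture
def gauss():
    return gaussian_spectrum
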