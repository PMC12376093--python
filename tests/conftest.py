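import numpy as np
import pytest

import tdskit as tk


@pytest.fixture
def axis():
    """A 1 cm^-1 grid over the amide I' window."""
    return np.arange(1500.0, 1751.0, 1.0)


@pytest.fixture
def gaussian_band(axis):
    """Noiseless unit-height Gaussian band at 1623 cm^-1 (FWHM 24)."""
    return tk.Spectrum1D(
        axis, np.exp(-4 * np.log(2) * (axis - 1623.0) ** 2 / 24.0**2), role="od"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_spectrum(rng, n=None):
    """A random but valid Spectrum1D (sorted positive axis, finite values)."""
    n = n or int(rng.integers(3, 60))
    ax = np.sort(rng.uniform(800.0, 4000.0, n))
    while np.any(np.diff(ax) == 0):  # pragma: no cover - vanishing probability
        ax = np.sort(rng.uniform(800.0, 4000.0, n))
    return tk.Spectrum1D(ax, rng.normal(0.0, 1.0, n))
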