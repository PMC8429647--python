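import numpy as np
import pytest

from marginspec.core import Modality, SpectralDataset, Spectrum, WavenumberAxis


@pytest.fixture
def ftir_axis():
    """Standard FT-IR axis: 900-3800 cm^-1 at 4 cm^-1 (726 points)."""
    return WavenumberAxis(np.arange(900.0, 3801.0, 4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def gaussian_band(x, center, fwhm, height=1.0):
    return height * np.exp(-4 * np.log(2) * ((x - center) / fwhm) ** 2)


@pytest.fixture
def band_spectrum(ftir_axis):
    """Single Gaussian band near 1650 on a zero baseline."""
    y = gaussian_band(ftir_axis.values, 1650.0, 60.0, 1.0)
    return Spectrum(ftir_axis, y, Modality.FTIR)


def make_dataset(axis, intensities, labels, modality=Modality.FTIR):
    import pandas as pd

    meta = pd.DataFrame({"tissue": labels})
    return SpectralDataset(axis, np.asarray(intensities), modality, meta)
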