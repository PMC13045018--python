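import numpy as np
import pytest

from pyrosom.spectra_io import LibraryEntry, Spectrum


def make_spectrum(pairs, rt=0.0):
    """Spectrum from {mz: intensity} or [(mz, intensity), ...]."""
    items = sorted(pairs.items() if isinstance(pairs, dict) else pairs)
    mz = np.array([m for m, _ in items], dtype=float)
    inten = np.array([i for _, i in items], dtype=float)
    return Spectrum(mz, inten, rt=rt)


@pytest.fixture
def toluene_phenol_library():
    return [
        LibraryEntry("Toluene",
                     make_spectrum({39: 120, 51: 45, 65: 110, 91: 999, 92: 612}),
                     "MAH"),
        LibraryEntry("Phenol",
                     make_spectrum({39: 200, 65: 230, 66: 210, 94: 999}),
                     "phenols"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
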