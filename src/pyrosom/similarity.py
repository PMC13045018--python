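"""Spectral cosine similarity on the unit-mass grid.

Shared by alignment (pair scores), annotation (library matching) and
networking (edge weights); all three use the same measure so a single
threshold value means the same thing at every stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import UndefinedSimilarityError
from .spectra_io import Spectrum, unit_mass_vector


def cosine(a: Spectrum, b: Spectrum, mz_power: float = 0.0,
           intensity_power: float = 1.0) -> float:
    """Cosine similarity of two spectra on the integer m/z grid.

    Peaks are summed into unit-mass bins and the normalized dot product is
    returned: symmetric, in [0, 1] for non-negative intensities, and
    invariant to uniform intensity scaling of either spectrum.
    ``intensity_power`` optionally compresses (<1) or stretches (>1)
    intensities before comparison; ``mz_power`` applies NIST-style m/z
    weighting. Both default to plain cosine on raw intensities.
    """
    lo = int(min(a.mz.min(), b.mz.min()))
    hi = int(max(a.mz.max(), b.mz.max())) + 1
    va = unit_mass_vector(a, lo, hi)
    vb = unit_mass_vector(b, lo, hi)
    if intensity_power != 1.0:
        va, vb = va ** intensity_power, vb ** intensity_power
    if mz_power != 0.0:
        w = np.arange(lo, hi + 1, dtype=float) ** mz_power
        va, vb = va * w, vb * w
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError(
            "cosine similarity is undefined for an all-zero spectrum"
        )
    return float(np.dot(va, vb) / (na * nb))


def _grid_matrix(spectra: Sequence[Spectrum], lo: int, hi: int) -> np.ndarray:
    M = np.vstack([unit_mass_vector(s, lo, hi) for s in spectra])
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise UndefinedSimilarityError("all-zero spectrum in similarity batch")
    return M / norms


def cosine_matrix(
    rows: Sequence[Spectrum], cols: Sequence[Spectrum] | None = None
) -> np.ndarray:
    """All pairwise cosines, vectorized on a shared unit-mass grid."""
    sym = cols is None
    cols = rows if sym else cols
    lo = int(min(min(s.mz.min() for s in rows), min(s.mz.min() for s in cols)))
    hi = int(max(max(s.mz.max() for s in rows), max(s.mz.max() for s in cols))) + 1
    R = _grid_matrix(rows, lo, hi)
    C = R if sym else _grid_matrix(cols, lo, hi)
    return np.clip(R @ C.T, 0.0, 1.0)
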