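"""Chromatogram building, peak detection, and MCR-ALS deconvolution.

A pyrolysis run is reduced to unit-mass extracted-ion chromatograms (EICs),
peaks are detected per EIC with height and signal-to-noise gates, and
co-eluting components are resolved window-by-window with non-negative
alternating least squares (MCR-ALS): the scans x m/z intensity matrix of a
retention-time window is factorized as X ~ C S^T with non-negative elution
profiles C and component spectra S.

Defaults follow the workflow this package automates: intensity threshold
1e5 counts for EIC existence, minimum feature height 1e5, S/N >= 5, and a
0.05 min retention-time tolerance for grouping co-eluting peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ParameterError
from .spectra_io import BASE_PEAK_NORM, Run, Spectrum, spectrum_from_vector


@dataclass
class EIC:
    """Extracted-ion chromatogram of one nominal (integer) m/z bin."""

    mz: int
    rts: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.rts) <= 0):
            raise ParameterError("EIC retention times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ParameterError("EIC intensities must be non-negative")


@dataclass
class Peak:
    """A detected chromatographic peak within one EIC."""

    mz: int
    apex_rt: float
    height: float
    left: int   # index of the left flanking minimum
    right: int  # index of the right flanking minimum (inclusive)
    apex_index: int


@dataclass
class Feature:
    """A deconvoluted pyrolysate within one sample."""

    rt: float
    spectrum: Spectrum
    height: float
    area: float
    sample_id: str = ""
    feature_id: str = ""

    def __post_init__(self) -> None:
        if len(self.spectrum) == 0:
            raise ParameterError("feature spectrum must be non-empty")


def run_matrix(run: Run) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense scans x unit-mass matrix of a run.

    Returns ``(X, rts, mz_bins)`` where ``X[i, j]`` is the summed intensity
    of scan ``i`` in nominal-mass bin ``mz_bins[j]``.
    """
    lo, hi = (int(b) for b in run.scan_range)
    bins = np.arange(lo, hi + 1)
    X = np.zeros((len(run.scans), len(bins)))
    for i, scan in enumerate(run.scans):
        idx = np.rint(scan.mz).astype(int) - lo
        ok = (idx >= 0) & (idx < len(bins))
        np.add.at(X[i], idx[ok], scan.intensity[ok])
    return X, run.rts, bins


def build_eics(run: Run, intensity_threshold: float = 1e5) -> list[EIC]:
    """One EIC per integer m/z bin whose trace reaches the intensity threshold.

    The threshold gates EIC *existence* only: a bin qualifies if at least one
    scan point is >= threshold, and the full trace (including sub-threshold
    points) is retained for qualifying bins.
    """
    if intensity_threshold <= 0:
        raise ParameterError("intensity_threshold must be > 0")
    if len(run.scans) == 0:
        return []
    X, rts, bins = run_matrix(run)
    keep = np.nonzero(X.max(axis=0) >= intensity_threshold)[0]
    return [EIC(int(bins[j]), rts, X[:, j]) for j in keep]


def estimate_noise(trace: np.ndarray) -> float:
    """Robust noise sigma: scaled MAD of the trace's first differences.

    Differencing removes slowly varying peak structure; the 1.4826 factor
    makes the MAD consistent with a Gaussian sigma, and the sqrt(2) divides
    out the variance doubling introduced by differencing.
    """
    d = np.diff(trace)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(
    eic: EIC, min_sn: float = 5.0, min_height: float = 1e5
) -> list[Peak]:
    """Local maxima of an EIC passing the height and S/N gates.

    Peak bounds are the nearest flanking local minima (or trace ends).
    """
    if min_sn < 1:
        raise ParameterError("min_sn must be >= 1")
    if min_height <= 0:
        raise ParameterError("min_height must be > 0")
    y = eic.intensities
    n = len(y)
    if n < 3:
        return []
    noise = estimate_noise(y)
    apexes = [
        i for i in range(1, n - 1)
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] >= min_height
        and (noise == 0.0 or y[i] / noise >= min_sn)
    ]
    peaks: list[Peak] = []
    for i in apexes:
        left = i
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
        right = i
        while right < n - 1 and y[right + 1] < y[right]:
            right += 1
        peaks.append(Peak(eic.mz, float(eic.rts[i]), float(y[i]), left, right, i))
    return peaks


def _cluster_1d(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """Single-linkage clusters of sorted 1-D points; a gap > ``gap`` splits."""
    order = np.argsort(values, kind="stable")
    groups: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if values[cur] - values[prev] > gap:
            groups.append([])
        groups[-1].append(cur)
    return [np.array(g) for g in groups]


def _als(
    X: np.ndarray,
    S0: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Non-negative alternating least squares X ~ C S^T.

    ``S0`` (n_mz x k) seeds the spectra; each half-step is an exact
    non-negative least-squares solve, so the residual never increases.
    Returns (C, S, relative residual, residual history).
    """
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        k = S0.shape[1]
        return np.zeros((X.shape[0], k)), S0, 0.0, [0.0]
    S = S0.copy()
    k = S.shape[1]
    C = np.zeros((X.shape[0], k))
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        for i in range(X.shape[0]):
            C[i], _ = nnls(S, X[i])
        for j in range(X.shape[1]):
            S[j], _ = nnls(C, X[:, j])
        resid = np.linalg.norm(X - C @ S.T) / norm_x
        history.append(resid)
        if prev - resid < tol:
            break
        prev = resid
    else:
        warnings.warn(
            f"MCR-ALS did not converge within {max_iter} iterations "
            f"(relative residual {history[-1]:.3g}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return C, S, history[-1], history


def resolve_components(
    eics: Sequence[EIC],
    peaks: Sequence[Peak],
    rt_tol: float = 0.05,
    apex_gap: float = 0.01,
    min_height: float = 1e5,
    sample_id: str = "",
    max_iter: int = 200,
    tol: float = 1e-6,
    rank_tol: float = 0.01,
    max_extra_components: int = 2,
    collect_residuals: list[float] | None = None,
) -> list[Feature]:
    """Resolve detected peaks into deconvoluted Features via MCR-ALS.

    Peak apexes are grouped twice by single-linkage clustering on retention
    time: gaps > ``rt_tol`` delimit independent windows, and within each
    window gaps > ``apex_gap`` delimit distinct components (fragments of one
    compound apex within a scan or two of each other; distinct co-eluting
    compounds sit several scans apart). Each window's scans x m/z matrix is
    factorized with non-negative ALS into as many components as apex
    sub-clusters; each component becomes one Feature with its spectrum
    normalized to base peak 999 and height/area taken from its elution
    profile at the base-peak scale.
    """
    if rt_tol <= 0:
        raise ParameterError("rt_tol must be > 0")
    if apex_gap <= 0 or apex_gap > rt_tol:
        raise ParameterError("apex_gap must be in (0, rt_tol]")
    if not peaks:
        return []
    eic_by_mz = {e.mz: e for e in eics}
    rts = next(iter(eic_by_mz.values())).rts
    apex_rts = np.array([p.apex_rt for p in peaks])

    features: list[Feature] = []
    windows = _cluster_1d(apex_rts, rt_tol)  # ascending apex order
    # clip adjacent windows at the midpoint between their apex groups so one
    # window's matrix never contains a neighboring component's peak region
    bounds: list[tuple[float, float]] = []
    for w, idx in enumerate(windows):
        lo_rt = -np.inf if w == 0 else (
            (apex_rts[windows[w - 1]].max() + apex_rts[idx].min()) / 2.0
        )
        hi_rt = np.inf if w == len(windows) - 1 else (
            (apex_rts[idx].max() + apex_rts[windows[w + 1]].min()) / 2.0
        )
        bounds.append((lo_rt, hi_rt))
    for window_idx, (lo_rt, hi_rt) in zip(windows, bounds):
        window_peaks = [peaks[i] for i in window_idx]
        sub = _cluster_1d(np.array([p.apex_rt for p in window_peaks]), apex_gap)
        lo = min(p.left for p in window_peaks)
        hi = max(p.right for p in window_peaks) + 1
        lo = max(lo, int(np.searchsorted(rts, lo_rt, side="left")))
        hi = min(hi, int(np.searchsorted(rts, hi_rt, side="right")))
        mzs = sorted({p.mz for p in window_peaks})
        X = np.column_stack([eic_by_mz[m].intensities[lo:hi] for m in mzs])
        # seed each component's spectrum from the scan at its apex cluster
        S0 = np.zeros((len(mzs), len(sub)))
        apex_rows = []
        for j, cluster in enumerate(sub):
            cpeaks = [window_peaks[i] for i in cluster]
            apex = max(cpeaks, key=lambda p: p.height)
            row = apex.apex_index - lo
            apex_rows.append(row)
            S0[:, j] = np.maximum(X[row], 0)
        C, S, resid, _ = _als(X, S0, max_iter=max_iter, tol=tol)
        # component-count selection: a poor fit means the apex clustering
        # under-counted (e.g. a shared fragment bridged two apex groups);
        # add components seeded from the worst-fit scan until the data are
        # reconstructed or the budget is exhausted
        extra = 0
        while resid > rank_tol and extra < max_extra_components:
            R = X - C @ S.T
            row = int(np.argmax(np.linalg.norm(R, axis=1)))
            S0_new = np.column_stack([S, np.maximum(R[row], 0)])
            if S0_new[:, -1].max() <= 0:
                break
            C2, S2, resid2, _ = _als(X, S0_new, max_iter=max_iter, tol=tol)
            if resid2 >= resid:
                break
            C, S, resid = C2, S2, resid2
            extra += 1
        if collect_residuals is not None:
            collect_residuals.append(resid)
        for j in range(S.shape[1]):
            s_col, c_col = S[:, j], C[:, j]
            s_max = s_col.max()
            if s_max <= 0 or c_col.max() <= 0:
                continue
            # base-peak trace of this component; its apex is the height
            trace = c_col * s_max
            apex_row = int(np.argmax(c_col))
            height = float(trace[apex_row])
            if height < min_height:
                continue
            area = float(np.trapezoid(trace, rts[lo:hi]))
            vec = s_col * (BASE_PEAK_NORM / s_max)
            vec[vec < 1e-9 * BASE_PEAK_NORM] = 0.0  # strip ALS dust
            spec_vec = np.zeros(int(max(mzs)) + 1)
            spec_vec[np.array(mzs)] = vec
            spectrum = spectrum_from_vector(spec_vec, lo=0,
                                            rt=float(rts[lo + apex_row]))
            features.append(Feature(
                rt=float(rts[lo + apex_row]),
                spectrum=spectrum,
                height=height,
                area=area,
                sample_id=sample_id,
            ))
    features.sort(key=lambda f: f.rt)
    for i, f in enumerate(features):
        f.feature_id = f"{sample_id or 'S'}:{i}"
    return features


def deconvolve(
    run: Run,
    intensity_threshold: float = 1e5,
    min_sn: float = 5.0,
    min_height: float = 1e5,
    rt_tol: float = 0.05,
    apex_gap: float = 0.01,
    sample_id: str = "",
) -> list[Feature]:
    """Full per-sample chain: EICs -> peak detection -> MCR-ALS features."""
    eics = build_eics(run, intensity_threshold)
    peaks = [p for e in eics for p in detect_peaks(e, min_sn, min_height)]
    return resolve_components(
        eics, peaks, rt_tol=rt_tol, apex_gap=apex_gap,
        min_height=min_height, sample_id=sample_id,
    )


def feature_table(features: Sequence[Feature]) -> pd.DataFrame:
    """Delimited-text-ready summary of deconvoluted features."""
    return pd.DataFrame([
        {
            "feature_id": f.feature_id,
            "sample_id": f.sample_id,
            "rt_min": f.rt,
            "height": f.height,
            "area": f.area,
            "base_peak_mz": f.spectrum.base_peak_mz,
            "n_fragments": len(f.spectrum),
        }
        for f in features
    ])


def write_feature_table(features: Sequence[Feature], path: str | Path) -> None:
    feature_table(features).to_csv(path, index=False)
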