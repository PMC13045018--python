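"""Cross-sample alignment of deconvoluted features.

Features from different samples (or replicate injections of one sample)
are grouped when a blended retention-time / spectral-similarity score
clears a threshold:

    score = w_rt * max(0, 1 - |dRT| / rt_tol) + (1 - w_rt) * cosine(spectra)

with defaults w_rt = 0.5, rt_tol = 0.05 min and threshold 0.7. Merging is
greedy best-pair-first, never joins two features from the same sample, and
leaves unmatched features as singleton groups, so the output is always a
partition of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import Feature
from .errors import ParameterError
from .similarity import cosine, cosine_matrix
from .spectra_io import (
    BASE_PEAK_NORM,
    LibraryEntry,
    Spectrum,
    spectrum_from_vector,
    unit_mass_vector,
    write_mgf,
)


@dataclass
class AlignedFeature:
    """A cross-sample group of mutually matched features."""

    node_id: str
    members: list[Feature]
    consensus_spectrum: Spectrum
    rt: float
    per_sample_height: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError("aligned feature needs at least one member")
        samples = [m.sample_id for m in self.members]
        if len(samples) != len(set(samples)):
            raise ParameterError("two members share a sample_id")


def pair_score(a: Feature, b: Feature, rt_tol: float = 0.05,
               w_rt: float = 0.5) -> float:
    """Blended RT-proximity / spectral-cosine score in [0, 1]."""
    rt_term = max(0.0, 1.0 - abs(a.rt - b.rt) / rt_tol)
    return w_rt * rt_term + (1.0 - w_rt) * cosine(a.spectrum, b.spectrum)


def _consensus(members: Sequence[Feature]) -> Spectrum:
    """Height-weighted mean of member spectra on the unit-mass grid."""
    lo = int(min(m.spectrum.mz.min() for m in members))
    hi = int(max(m.spectrum.mz.max() for m in members)) + 1
    acc = np.zeros(hi - lo + 1)
    total = 0.0
    for m in members:
        v = unit_mass_vector(m.spectrum, lo, hi)
        peak = v.max()
        if peak > 0:
            acc += (v / peak) * m.height
            total += m.height
    acc /= max(total, 1e-300)
    acc *= BASE_PEAK_NORM / acc.max()
    rt = float(np.mean([m.rt for m in members]))
    return spectrum_from_vector(acc, lo=lo, rt=rt)


def align(
    features: Mapping[str, Sequence[Feature]],
    score_threshold: float = 0.7,
    rt_tol: float = 0.05,
    w_rt: float = 0.5,
    all_samples: Sequence[str] | None = None,
) -> list[AlignedFeature]:
    """Group per-sample features into AlignedFeatures.

    Parameters
    ----------
    features
        Map sample_id -> list of that sample's deconvoluted features.
    score_threshold
        Minimum pair score for a merge (default 0.7).
    rt_tol
        Retention-time tolerance in minutes (default 0.05).
    w_rt
        Weight of the RT term in the score (default 0.5).
    all_samples
        Sample ids to report heights for (defaults to the keys of
        ``features``); absent samples get height 0.

    Every input feature ends up in exactly one group; features never merged
    above the threshold become singletons. Candidate pairs are processed in
    descending score order (ties: lower mean rt, then sample/feature ids),
    and a merge is accepted only if the two groups share no sample.
    """
    if not 0 < score_threshold <= 1:
        raise ParameterError("score_threshold must be in (0, 1]")
    if rt_tol <= 0:
        raise ParameterError("rt_tol must be > 0")
    if not 0 <= w_rt <= 1:
        raise ParameterError("w_rt must be in [0, 1]")
    samples = list(all_samples) if all_samples is not None else sorted(features)
    flat: list[Feature] = []
    for sid in sorted(features):
        flat.extend(features[sid])
    n = len(flat)
    if n == 0:
        return []

    # pair scores: vectorized cosine, RT term added per pair
    cos = cosine_matrix([f.spectrum for f in flat])
    rts = np.array([f.rt for f in flat])
    sample_of = [f.sample_id for f in flat]
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            if sample_of[i] == sample_of[j]:
                continue
            rt_term = max(0.0, 1.0 - abs(rts[i] - rts[j]) / rt_tol)
            s = w_rt * rt_term + (1.0 - w_rt) * cos[i, j]
            if s >= score_threshold:
                candidates.append((
                    -s, (rts[i] + rts[j]) / 2.0,
                    sample_of[i], sample_of[j], i, j,
                ))
    candidates.sort()

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    group_samples: dict[int, set[str]] = {i: {sample_of[i]} for i in range(n)}
    for _, _, _, _, i, j in candidates:
        ri, rj = find(i), find(j)
        if ri == rj or group_samples[ri] & group_samples[rj]:
            continue
        parent[rj] = ri
        group_samples[ri] |= group_samples.pop(rj)

    groups: dict[int, list[Feature]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(flat[i])
    aligned = []
    for members in groups.values():
        members.sort(key=lambda f: f.sample_id)
        heights = {sid: 0.0 for sid in samples}
        for m in members:
            heights[m.sample_id] = m.height
        aligned.append(AlignedFeature(
            node_id="",
            members=members,
            consensus_spectrum=_consensus(members),
            rt=float(np.mean([m.rt for m in members])),
            per_sample_height=heights,
        ))
    aligned.sort(key=lambda g: (g.rt, g.members[0].sample_id))
    for k, g in enumerate(aligned):
        g.node_id = f"AF{k:04d}"
    return aligned


def quantification_table(aligned: Sequence[AlignedFeature]) -> pd.DataFrame:
    """Aligned features x samples height matrix (the quantification table)."""
    samples = sorted({s for g in aligned for s in g.per_sample_height})
    rows = []
    for g in aligned:
        row: dict[str, object] = {"node_id": g.node_id, "rt_min": g.rt,
                                  "n_samples": len(g.members)}
        for sid in samples:
            row[sid] = g.per_sample_height.get(sid, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_quantification_table(aligned: Sequence[AlignedFeature],
                               path: str | Path) -> None:
    quantification_table(aligned).to_csv(path, index=False)


def write_consensus_mgf(aligned: Sequence[AlignedFeature],
                        path: str | Path) -> None:
    """Export consensus spectra as MGF for molecular networking."""
    write_mgf(
        [LibraryEntry(g.node_id, g.consensus_spectrum) for g in aligned], path
    )
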