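"""Synthetic py-GC/MS and EGA data with known ground truth.

Generates EI fragment spectra organized into structural families (fragment
sharing within a family keeps within-family cosine high and cross-family
cosine low), raw runs as Gaussian elution peaks over a noisy baseline,
reference libraries, and multi-ecosystem sample designs with a shared
compound core, ecosystem-specific tails and a wetland-exclusive set.

Every generator is deterministic under a fixed seed, and all outputs
satisfy the package's container invariants, so each pipeline stage can be
benchmarked against planted truth without external data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import Feature
from .errors import ParameterError
from .spectra_io import (
    BASE_PEAK_NORM,
    DEFAULT_CLASSES,
    ClassLibrary,
    LibraryEntry,
    Run,
    Spectrum,
)

#: Ecosystem labels used by :func:`gen_design`; the first two are wetlands.
ECOSYSTEM_NAMES = ("vernal_pool", "prairie_pothole", "forest", "grassland",
                   "tropical")

#: Default Gaussian elution width (sd, minutes) — narrow enough that the
#: 0.05 min alignment tolerance is meaningfully stressed by co-elution.
ELUTION_SIGMA = 0.02

#: Default scan spacing in minutes (0.3 s scan time).
SCAN_INTERVAL_MIN = 0.005


@dataclass
class SyntheticCompound:
    """A planted pyrolysate with known spectrum, class and elution."""

    name: str
    spectrum: Spectrum                   # base peak normalized to 999
    rt: float                            # apex retention time, minutes
    height: float                        # apex base-peak intensity, counts
    compound_class: str
    family_id: str

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ParameterError("height must be > 0")


def _family_seed(family: str) -> int:
    return zlib.crc32(family.encode()) & 0x7FFFFFFF


def _family_base(family: str) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic base fragment set (mz, intensity) for a family."""
    rng = np.random.default_rng(_family_seed(family))
    n = int(rng.integers(12, 26))
    mz = np.sort(rng.choice(np.arange(50, 451), size=n, replace=False))
    inten = rng.exponential(scale=200.0, size=n) + 20.0
    inten *= BASE_PEAK_NORM / inten.max()
    return mz.astype(float), inten


def gen_compound(
    seed: int,
    family: str,
    compound_class: str | None = None,
    name: str | None = None,
) -> SyntheticCompound:
    """One compound from a structural family, deterministic given ``seed``.

    Compounds of the same family keep >= 75% of the family's fragment m/z
    (with log-normally perturbed intensities) plus a few private fragments,
    so within-family cosine stays high (> 0.7 in expectation) while
    compounds from unrelated families rarely share fragments.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, _family_seed(family)])
    base_mz, base_int = _family_base(family)
    n = len(base_mz)
    # always keep the family's dominant fragments; drop only from the tail
    n_keep = max(int(np.ceil(0.9 * n)), 1)
    strong = np.argsort(base_int)[-3:]
    weak_pool = np.setdiff1d(np.arange(n), strong)
    keep = np.sort(np.r_[strong, rng.choice(
        weak_pool, size=max(n_keep - len(strong), 0), replace=False)])
    mz = base_mz[keep]
    inten = base_int[keep] * rng.lognormal(0.0, 0.15, size=len(keep))
    n_extra = int(rng.integers(0, 4))
    if n_extra:
        pool = np.setdiff1d(np.arange(50, 451), mz.astype(int))
        extra_mz = rng.choice(pool, size=n_extra, replace=False).astype(float)
        extra_int = rng.uniform(10.0, 120.0, size=n_extra)
        mz = np.r_[mz, extra_mz]
        inten = np.r_[inten, extra_int]
    order = np.argsort(mz)
    spec = Spectrum(mz[order], inten[order]).normalized()
    cls = compound_class or str(rng.choice(DEFAULT_CLASSES))
    return SyntheticCompound(
        name=name or f"{family}_cpd{int(seed)}",
        spectrum=spec,
        rt=float(rng.uniform(1.0, 9.0)),
        height=float(10 ** rng.uniform(5.7, 7.0)),
        compound_class=cls,
        family_id=family,
    )


def gen_compound_set(
    n_compounds: int,
    n_families: int = 4,
    seed: int = 0,
    class_per_family: Mapping[str, str] | None = None,
) -> list[SyntheticCompound]:
    """A pool of compounds spread round-robin over ``n_families`` families."""
    rng = np.random.default_rng(seed)
    families = [f"fam{seed}_{k}" for k in range(n_families)]
    cls_of = dict(class_per_family or {})
    for fam in families:
        cls_of.setdefault(fam, str(rng.choice(DEFAULT_CLASSES)))
    return [
        gen_compound(int(rng.integers(0, 2**31 - 1)), families[i % n_families],
                     compound_class=cls_of[families[i % n_families]],
                     name=f"compound_{seed}_{i:03d}")
        for i in range(n_compounds)
    ]


def gen_library(
    compounds: Sequence[SyntheticCompound],
) -> tuple[list[LibraryEntry], ClassLibrary]:
    """Reference spectral library + class table matching a compound pool."""
    entries = [LibraryEntry(c.name, c.spectrum, c.compound_class)
               for c in compounds]
    classes = ClassLibrary({c.name: c.compound_class for c in compounds})
    return entries, classes


@dataclass
class RunTruth:
    """Planted ground truth for one synthetic run."""

    compounds: list[SyntheticCompound]
    co_eluting: list[tuple[str, str]] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "name": c.name, "rt": c.rt, "height": c.height,
                "class": c.compound_class, "family": c.family_id,
                "base_peak_mz": c.spectrum.base_peak_mz,
                "n_fragments": len(c.spectrum),
            }
            for c in self.compounds
        ])


def gen_run(
    compounds: Sequence[SyntheticCompound],
    noise_sd: float = 0.0,
    co_elute_pairs: int = 0,
    seed: int = 0,
    peak_sigma: float = ELUTION_SIGMA,
    scan_interval: float = SCAN_INTERVAL_MIN,
    rt_spacing: float = 0.15,
    baseline: float = 2.0,
    mode: str = "pyrolysis",
) -> tuple[Run, RunTruth]:
    """Simulate a raw run: Gaussian elution peaks over a noisy baseline.

    Compounds are laid out ``rt_spacing`` minutes apart (jittered), then
    the first ``co_elute_pairs`` consecutive pairs are pushed to apex
    separations of 0.025-0.05 min to stress deconvolution at the 0.05 min
    retention-time tolerance. Each compound contributes
    ``height * exp(-(t - rt)^2 / (2 peak_sigma^2))`` times its normalized
    spectrum; additive Gaussian noise (sd ``noise_sd``) and a flat
    ``baseline`` keep every scan non-empty. Returns the run and the planted
    truth (with the final, possibly shifted, retention times).
    """
    if co_elute_pairs * 2 > len(compounds):
        raise ParameterError("not enough compounds for the requested pairs")
    rng = np.random.default_rng(seed)
    placed: list[SyntheticCompound] = []
    co_eluting: list[tuple[str, str]] = []
    t = 1.0
    i = 0
    k = 0
    while i < len(compounds):
        c = compounds[i]
        rt_a = t + rng.uniform(-0.01, 0.01)
        placed.append(SyntheticCompound(c.name, c.spectrum, rt_a, c.height,
                                        c.compound_class, c.family_id))
        if k < co_elute_pairs and i + 1 < len(compounds):
            d = compounds[i + 1]
            rt_b = rt_a + rng.uniform(0.025, 0.05)
            placed.append(SyntheticCompound(d.name, d.spectrum, rt_b, d.height,
                                            d.compound_class, d.family_id))
            co_eluting.append((c.name, d.name))
            i += 2
            k += 1
        else:
            i += 1
        t += rt_spacing
    t_end = max(c.rt for c in placed) + 0.3
    times = np.arange(0.5, t_end, scan_interval)
    lo, hi = (29, 850) if mode == "pyrolysis" else (29, 650)
    bins = np.arange(lo, hi + 1)
    X = np.full((len(times), len(bins)), float(baseline))
    for c in placed:
        profile = c.height * np.exp(-((times - c.rt) ** 2) /
                                    (2.0 * peak_sigma ** 2))
        idx = np.rint(c.spectrum.mz).astype(int) - lo
        ok = (idx >= 0) & (idx < len(bins))
        X[:, idx[ok]] += np.outer(profile,
                                  c.spectrum.intensity[ok] / BASE_PEAK_NORM)
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=X.shape)
        np.clip(X, 0.0, None, out=X)
    scans = [
        Spectrum(bins[row > 0].astype(float), row[row > 0], rt=float(times[j]))
        for j, row in enumerate(X)
    ]
    run = Run(scans, mode=mode, scan_interval=scan_interval * 60.0)
    return run, RunTruth(placed, co_eluting)


@dataclass
class DesignTruth:
    """Planted truth for a multi-ecosystem sample design."""

    compounds: list[SyntheticCompound]
    presence: pd.DataFrame               # compounds x ecosystems, bool
    ecosystems: list[str]
    wetlands: list[str]
    wetland_exclusive: list[str]         # compound names only in wetlands
    sample_to_ecosystem: dict[str, str]

    @property
    def classes(self) -> dict[str, str]:
        return {c.name: c.compound_class for c in self.compounds}


def gen_design(
    ecosystems: int = 5,
    samples_per: int = 3,
    shared_fraction: float = 0.3,
    wetland_exclusive: int = 24,
    n_compounds: int = 60,
    seed: int = 0,
    n_families: int = 6,
) -> tuple[dict[str, list[Feature]], DesignTruth]:
    """Multi-sample feature sets with a planted presence structure.

    The compound pool has a globally shared core (``shared_fraction`` of
    ``n_compounds``), ecosystem-specific tails, and ``wetland_exclusive``
    additional compounds present only in the two wetland ecosystems.
    Abundances are log-normal (sigma = 1 on the log scale) per compound,
    with milder replicate-level jitter. Returns per-sample deconvolved-
    feature lists (noiseless detection) and the planted truth.
    """
    if not 0 <= shared_fraction <= 1:
        raise ParameterError("shared_fraction must be in [0, 1]")
    if ecosystems < 1:
        raise ParameterError("need at least one ecosystem")
    rng = np.random.default_rng(seed)
    eco_names = [
        ECOSYSTEM_NAMES[i] if i < len(ECOSYSTEM_NAMES) else f"eco{i}"
        for i in range(ecosystems)
    ]
    wetlands = eco_names[: min(2, ecosystems)]
    uplands = [e for e in eco_names if e not in wetlands]

    pool = gen_compound_set(n_compounds + wetland_exclusive,
                            n_families=n_families, seed=seed)
    # respace apexes 0.1 min apart so distinct compounds never fall inside
    # the 0.05 min alignment tolerance of one another
    for i, c in enumerate(pool):
        c.rt = 1.0 + 0.1 * i
    n_shared = int(round(shared_fraction * n_compounds))
    presence: dict[str, set[str]] = {}
    # tails are ecosystem-specific; when a wetland-exclusive set is planted
    # they stay out of the wetlands so that set alone is wetland-only
    tail_pool = uplands if (wetland_exclusive > 0 and uplands) else eco_names
    for i, c in enumerate(pool[:n_compounds]):
        if i < n_shared:
            presence[c.name] = set(eco_names)
        else:
            presence[c.name] = {tail_pool[(i - n_shared) % len(tail_pool)]}
    exclusive = pool[n_compounds:]
    for c in exclusive:
        presence[c.name] = set(wetlands)

    base_abundance = {
        c.name: float(np.exp(rng.normal(np.log(c.height), 1.0)))
        for c in pool
    }
    features: dict[str, list[Feature]] = {}
    sample_to_eco: dict[str, str] = {}
    for eco in eco_names:
        for rep in range(samples_per):
            sid = f"{eco}_r{rep + 1}"
            sample_to_eco[sid] = eco
            feats = []
            for c in pool:
                if eco not in presence[c.name]:
                    continue
                h = base_abundance[c.name] * float(rng.lognormal(0.0, 0.2))
                feats.append(Feature(
                    rt=c.rt,
                    spectrum=c.spectrum,
                    height=h,
                    area=h * ELUTION_SIGMA * np.sqrt(2 * np.pi),
                    sample_id=sid,
                    feature_id=f"{sid}:{c.name}",
                ))
            feats.sort(key=lambda f: f.rt)
            features[sid] = feats
    pres_df = pd.DataFrame(
        {eco: [eco in presence[c.name] for c in pool] for eco in eco_names},
        index=[c.name for c in pool],
    )
    truth = DesignTruth(
        compounds=list(pool),
        presence=pres_df,
        ecosystems=eco_names,
        wetlands=wetlands,
        wetland_exclusive=[c.name for c in exclusive],
        sample_to_ecosystem=sample_to_eco,
    )
    return features, truth
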