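"""Data model and I/O for EI fragmentation spectra.

Core containers (:class:`Spectrum`, :class:`Run`, :class:`LibraryEntry`,
:class:`ClassLibrary`) plus readers/writers for mzML (MS1 scans), MSP/MGF
spectral libraries, and the delimited compound-class table that maps
pyrolysate names onto the 12 compound classes used throughout the
pipeline.

Retention times are normalized to minutes everywhere, whatever the source
file used, because every downstream tolerance (e.g. the 0.05 min alignment
window) is expressed in minutes.
"""

from __future__ import annotations

import base64
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape

import zlib

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

from .errors import (
    ClassLibraryError,
    EmptyRunError,
    ParseError,
    SpectrumError,
)

#: Acquisition m/z windows per mode: the first quadrupole scans m/z 29-850
#: in pyrolysis-GC/MS mode and 29-650 in evolved-gas (EGA) mode.
SCAN_RANGES: dict[str, tuple[float, float]] = {
    "pyrolysis": (29.0, 850.0),
    "ega": (29.0, 650.0),
}

#: The 12 compound classes used for pyrolysate classification.
DEFAULT_CLASSES: tuple[str, ...] = (
    "alkenes",
    "degraded saccharides",
    "fatty acids, alcohols and esters",
    "lignin",
    "long alkanes",
    "MAH",
    "N-MAH",
    "other hydrocarbons",
    "other N-containing",
    "phenols",
    "PAH",
    "short alkanes",
)

#: Intensity of the base (largest) peak after normalization, NIST-style.
BASE_PEAK_NORM = 999.0


@dataclass
class Spectrum:
    """One EI fragmentation spectrum: stick (centroid) m/z-intensity pairs.

    Parameters
    ----------
    mz
        Mass-to-charge values in Th, strictly ascending.
    intensity
        Non-negative abundances, same length as ``mz``.
    rt
        Retention (or acquisition) time in minutes, >= 0.
    metadata
        Free-form key -> string map (sample id, instrument, ...).
    """

    mz: np.ndarray
    intensity: np.ndarray
    rt: float = 0.0
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise SpectrumError(
                f"length mismatch: {len(self.mz)} mz vs {len(self.intensity)} intensities"
            )
        if len(self.mz) == 0:
            raise SpectrumError("a spectrum needs at least one peak")
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumError("mz values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise SpectrumError("intensities must be non-negative")
        if float(self.rt) < 0:
            raise SpectrumError("retention time must be >= 0")
        self.rt = float(self.rt)

    def __len__(self) -> int:
        return len(self.mz)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
            and self.rt == other.rt
        )

    @property
    def base_peak_mz(self) -> float:
        return float(self.mz[int(np.argmax(self.intensity))])

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max())

    def normalized(self, top: float = BASE_PEAK_NORM) -> "Spectrum":
        """Scale so the base peak equals ``top`` (999 by convention)."""
        peak = self.intensity.max()
        if peak <= 0:
            raise SpectrumError("cannot normalize an all-zero spectrum")
        return Spectrum(self.mz.copy(), self.intensity * (top / peak), self.rt,
                        dict(self.metadata))

    def restricted(self, lo: float, hi: float) -> "Spectrum | None":
        """Drop peaks outside [lo, hi]; None if nothing survives."""
        keep = (self.mz >= lo) & (self.mz <= hi)
        if not keep.any():
            return None
        return Spectrum(self.mz[keep], self.intensity[keep], self.rt,
                        dict(self.metadata))


def unit_mass_vector(
    spec: Spectrum, lo: int = 29, hi: int = 850
) -> np.ndarray:
    """Project a spectrum onto the integer (unit-mass) m/z grid [lo, hi].

    Peaks rounding to the same nominal mass are summed; peaks outside the
    grid are dropped. Returns a dense vector of length ``hi - lo + 1``.
    """
    out = np.zeros(hi - lo + 1)
    bins = np.rint(spec.mz).astype(int)
    ok = (bins >= lo) & (bins <= hi)
    np.add.at(out, bins[ok] - lo, spec.intensity[ok])
    return out


def spectrum_from_vector(vec: np.ndarray, lo: int = 29, rt: float = 0.0,
                         metadata: Mapping[str, str] | None = None) -> Spectrum:
    """Inverse of :func:`unit_mass_vector`: keep the non-zero bins."""
    nz = np.nonzero(vec > 0)[0]
    if len(nz) == 0:
        raise SpectrumError("vector has no positive bins")
    return Spectrum((nz + lo).astype(float), vec[nz], rt,
                    dict(metadata or {}))


@dataclass
class Run:
    """A time-ordered sequence of MS1 scans from one acquisition."""

    scans: list[Spectrum]
    mode: str = "pyrolysis"
    scan_interval: float = 0.3  # seconds between scans

    def __post_init__(self) -> None:
        if self.mode not in SCAN_RANGES:
            raise SpectrumError(
                f"mode must be one of {sorted(SCAN_RANGES)}, got {self.mode!r}"
            )
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise SpectrumError("scan retention times must be non-decreasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    @property
    def scan_range(self) -> tuple[float, float]:
        return SCAN_RANGES[self.mode]

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class LibraryEntry:
    """A named reference spectrum, optionally carrying a class hint."""

    name: str
    spectrum: Spectrum
    class_hint: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise SpectrumError("library entry name must be non-empty")


_CAS_SUFFIX = re.compile(r",?\s*\(?\bCAS\b[^)]*\)?\s*$", re.IGNORECASE)
_CAS_NUMBER = re.compile(r",?\s*\d{2,7}-\d{2}-\d\s*$")


def normalize_compound_name(name: str) -> str:
    """Canonical form for compound-name matching.

    Case-insensitive, whitespace-collapsed, with trailing CAS-style
    registry suffixes stripped — NIST hit strings vary in all three.
    """
    s = _CAS_SUFFIX.sub("", name)
    s = _CAS_NUMBER.sub("", s)
    return " ".join(s.split()).lower()


class ClassLibrary:
    """Compound name -> compound class mapping over a permitted class set."""

    def __init__(
        self,
        entries: Mapping[str, str],
        classes: Iterable[str] | None = None,
    ) -> None:
        self.classes: frozenset[str] = frozenset(
            classes if classes is not None else DEFAULT_CLASSES
        )
        norm: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for compound, cls in entries.items():
            if cls not in self.classes:
                raise ClassLibraryError(
                    f"class {cls!r} for compound {compound!r} is not in the "
                    f"permitted class set"
                )
            key = normalize_compound_name(compound)
            if key in norm and norm[key] != cls:
                raise ClassLibraryError(
                    f"conflicting classes for compound {compound!r}: "
                    f"{norm[key]!r} vs {cls!r}"
                )
            norm[key] = cls
            self._display.setdefault(key, compound)
        self.entries: dict[str, str] = norm

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, compound: str) -> bool:
        return normalize_compound_name(compound) in self.entries

    def lookup(self, compound: str) -> str | None:
        """Class for a compound name, or None if not listed."""
        return self.entries.get(normalize_compound_name(compound))


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _centroid(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum picking for profile-mode scans."""
    if len(mz) < 3:
        return mz, inten
    keep = np.r_[
        inten[0] > inten[1],
        (inten[1:-1] >= inten[:-2]) & (inten[1:-1] > inten[2:]),
        inten[-1] > inten[-2],
    ] & (inten > 0)
    if not keep.any():
        return mz, inten
    return mz[keep], inten[keep]


# CV accessions understood by the minimal mzML reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"
_ACC_PROFILE = "MS:1000128"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: etree._Element, scan_id: str, path: str) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values)."""
    dtype: str | None = None
    compressed = False
    kind: str | None = None
    payload = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F64:
                dtype = "<f8"
            elif acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    if kind is None:
        return "other", np.empty(0)
    if dtype is None:
        raise ParseError(
            f"scan {scan_id!r} in {path}: binary array without a "
            f"recognized precision cvParam"
        )
    try:
        raw = base64.b64decode(payload)
        if compressed:
            raw = zlib.decompress(raw)
        values = np.frombuffer(raw, dtype=dtype).astype(float)
    except Exception as exc:
        raise ParseError(
            f"scan {scan_id!r} in {path}: cannot decode {kind} array: {exc}"
        ) from exc
    return kind, values


def _parse_mzml_scan(elem: etree._Element, path: str
                     ) -> tuple[int, float, bool, np.ndarray, np.ndarray]:
    """Extract (ms_level, rt_minutes, is_profile, mz, intensity)."""
    scan_id = elem.get("id", elem.get("index", "?"))
    ms_level = 1
    rt = None
    profile = False
    mz = inten = None
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value", "1"))
            elif acc == _ACC_PROFILE:
                profile = True
            elif acc == _ACC_SCAN_START:
                unit = (child.get("unitName") or "minute").lower()
                rt = float(child.get("value", "nan"))
                if unit.startswith("second"):
                    rt /= 60.0
        elif name == "binaryDataArray":
            kind, values = _decode_binary(child, scan_id, path)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if ms_level != 1:
        return ms_level, 0.0, profile, np.empty(0), np.empty(0)
    if mz is None or inten is None or rt is None or np.isnan(rt):
        raise ParseError(
            f"malformed scan {scan_id!r} in {path}: missing "
            f"{'m/z array' if mz is None else 'intensity array' if inten is None else 'scan start time'}"
        )
    if len(mz) != len(inten):
        raise ParseError(
            f"malformed scan {scan_id!r} in {path}: m/z and intensity "
            f"array lengths differ ({len(mz)} vs {len(inten)})"
        )
    return 1, rt, profile, mz, inten


def read_mzml(path: str | Path, mode: str = "pyrolysis") -> Run:
    """Load all MS1 scans from an mzML file into a :class:`Run`.

    Retention times are converted to minutes; peaks outside the mode's
    acquisition window (29-850 for pyrolysis, 29-650 for EGA) are dropped.
    Profile-mode scans are centroided by local-maximum picking. The reader
    handles 32/64-bit little-endian arrays, with or without zlib
    compression.
    """
    if mode not in SCAN_RANGES:
        raise SpectrumError(f"unknown mode {mode!r}")
    lo, hi = SCAN_RANGES[mode]
    scans: list[Spectrum] = []
    try:
        context = etree.iterparse(str(path), events=("end",),
                                  tag="{*}spectrum")
        for _, elem in context:
            ms_level, rt, profile, mz, inten = _parse_mzml_scan(elem, str(path))
            elem.clear()
            if ms_level != 1:
                continue
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            if profile:
                mz, inten = _centroid(mz, inten)
            keep = (mz >= lo) & (mz <= hi)
            if not keep.any():
                continue
            scans.append(Spectrum(mz[keep], inten[keep], rt))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"cannot parse mzML file {path}: {exc}") from exc
    if not scans:
        raise EmptyRunError(f"no MS1 scans with in-range peaks in {path}")
    interval = 0.3
    if len(scans) > 1:
        interval = float(np.median(np.diff([s.rt for s in scans]))) * 60.0
    return Run(scans, mode=mode, scan_interval=interval)


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    ).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.10g}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: Run, path: str | Path, run_id: str = "run1") -> None:
    """Write a Run as minimal mzML 1.1.0 (uncompressed 64-bit arrays)."""
    parts = [_MZML_HEADER.format(run_id=escape(run_id, {'"': "&quot;"}),
                                 count=len(run.scans))]
    for i, s in enumerate(run.scans):
        mz_b64, int_b64 = _b64(s.mz), _b64(s.intensity)
        parts.append(_MZML_SPECTRUM.format(
            index=i, scan=i + 1, n=len(s), rt=s.rt,
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64,
        ))
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


# ---------------------------------------------------------------------------
# MSP / MGF libraries
# ---------------------------------------------------------------------------

_PEAK_SPLIT = re.compile(r"[;,]\s*|\s+")


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Parse an MSP spectral library (Name: / Num Peaks: records).

    Each record must list exactly the number of peaks its ``Num Peaks:``
    line declares; a mismatch raises :class:`ParseError` naming the record.
    Optional ``Class:`` and ``RT:`` fields populate the entry's class hint
    and the spectrum's retention time (minutes).
    """
    entries: list[LibraryEntry] = []
    name: str | None = None
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    declared: int | None = None

    def flush() -> None:
        nonlocal name, fields, peaks, declared
        if name is None:
            return
        if declared is None:
            raise ParseError(f"record {name!r} has no 'Num Peaks:' line")
        if len(peaks) != declared:
            raise ParseError(
                f"record {name!r} declares {declared} peaks but lists {len(peaks)}"
            )
        order = sorted(range(len(peaks)), key=lambda i: peaks[i][0])
        mz = [peaks[i][0] for i in order]
        inten = [peaks[i][1] for i in order]
        rt = float(fields.get("rt", 0.0))
        meta = {k: v for k, v in fields.items() if k not in ("rt", "class")}
        spec = Spectrum(np.array(mz), np.array(inten), rt=rt, metadata=meta)
        entries.append(LibraryEntry(name, spec, fields.get("class")))
        name, fields, peaks, declared = None, {}, [], None

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            flush()
            continue
        m = re.match(r"([A-Za-z][A-Za-z0-9 _/#-]*):\s*(.*)", line)
        if m and not re.match(r"^\d", line):
            key, value = m.group(1).strip().lower(), m.group(2).strip()
            if key == "name":
                flush()
                name = value
            elif key == "num peaks":
                try:
                    declared = int(value)
                except ValueError as exc:
                    raise ParseError(
                        f"record {name!r}: bad Num Peaks value {value!r} "
                        f"(line {lineno})"
                    ) from exc
            else:
                fields[key] = value
            continue
        tokens = [t for t in _PEAK_SPLIT.split(line) if t]
        if len(tokens) % 2 != 0:
            raise ParseError(
                f"record {name!r}: malformed peak line {lineno}: {line!r}"
            )
        try:
            vals = [float(t) for t in tokens]
        except ValueError as exc:
            raise ParseError(
                f"record {name!r}: non-numeric peak line {lineno}: {line!r}"
            ) from exc
        peaks.extend(zip(vals[::2], vals[1::2]))
    flush()
    return entries


def write_msp(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    """Write library entries in MSP format (one blank-line-separated record each)."""
    lines: list[str] = []
    for e in entries:
        lines.append(f"Name: {e.name}")
        if e.class_hint:
            lines.append(f"Class: {e.class_hint}")
        if e.spectrum.rt:
            lines.append(f"RT: {e.spectrum.rt:.10g}")
        for k, v in e.spectrum.metadata.items():
            lines.append(f"{k.capitalize()}: {v}")
        lines.append(f"Num Peaks: {len(e.spectrum)}")
        for mz, inten in zip(e.spectrum.mz, e.spectrum.intensity):
            lines.append(f"{mz:.10g} {inten:.10g}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_mgf(path: str | Path) -> list[LibraryEntry]:
    """Read spectra from an MGF file (TITLE -> name, CLASS -> class hint)."""
    entries: list[LibraryEntry] = []
    with _mgf.read(str(path)) as reader:
        for i, rec in enumerate(reader):
            params = rec.get("params", {})
            name = str(params.get("title", f"spectrum_{i}"))
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else 0.0
            mz = np.asarray(rec["m/z array"], dtype=float)
            order = np.argsort(mz)
            spec = Spectrum(mz[order],
                            np.asarray(rec["intensity array"], dtype=float)[order],
                            rt=rt_min)
            cls = params.get("class")
            entries.append(LibraryEntry(name, spec, str(cls) if cls else None))
    return entries


def write_mgf(entries: Sequence[LibraryEntry], path: str | Path) -> None:
    spectra = []
    for e in entries:
        params: dict[str, object] = {"title": e.name,
                                     "rtinseconds": e.spectrum.rt * 60.0}
        if e.class_hint:
            params["class"] = e.class_hint
        spectra.append({
            "m/z array": e.spectrum.mz,
            "intensity array": e.spectrum.intensity,
            "params": params,
        })
    _mgf.write(spectra, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Compound-class table
# ---------------------------------------------------------------------------

def read_class_library(
    path: str | Path, classes: Iterable[str] | None = None
) -> ClassLibrary:
    """Load the compound -> class table (comma/tab autodetected, header required).

    Class names outside the default 12-class set are rejected unless an
    extended ``classes`` set is supplied. Exact duplicates are deduplicated;
    a compound listed with two different classes is an error naming every
    conflict.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pandas raises several parser error types
        raise ClassLibraryError(f"cannot parse class table {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "compound" not in cols or "class" not in cols:
        raise ClassLibraryError(
            f"class table {path} must have 'compound' and 'class' columns; "
            f"found {list(df.columns)}"
        )
    df = df[[cols["compound"], cols["class"]]].dropna()
    permitted = frozenset(classes if classes is not None else DEFAULT_CLASSES)
    seen: dict[str, str] = {}
    display: dict[str, str] = {}
    conflicts: list[str] = []
    for compound, cls in df.itertuples(index=False):
        compound, cls = str(compound).strip(), str(cls).strip()
        if cls not in permitted:
            raise ClassLibraryError(
                f"unknown class {cls!r} for compound {compound!r}; permitted "
                f"classes: {sorted(permitted)}"
            )
        key = normalize_compound_name(compound)
        if key in seen and seen[key] != cls:
            conflicts.append(f"{compound!r}: {seen[key]!r} vs {cls!r}")
        seen[key] = cls
        display.setdefault(key, compound)
    if conflicts:
        raise ClassLibraryError(
            "conflicting class assignments: " + "; ".join(conflicts)
        )
    return ClassLibrary({display[k]: v for k, v in seen.items()}, permitted)


def write_class_library(lib: ClassLibrary, path: str | Path) -> None:
    rows = [{"compound": lib._display[k], "class": v}
            for k, v in sorted(lib.entries.items())]
    pd.DataFrame(rows, columns=["compound", "class"]).to_csv(path, index=False)
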