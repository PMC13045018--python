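"""Evolved-gas analysis: thermal profiles from ramp-heated MS runs.

In EGA mode the sample is ramp-heated (default 100 °C with a 1 min hold,
then 10 °C/min to 900 °C) while all evolved gases pass unresolved to the
mass spectrometer. Scan times map linearly onto furnace temperatures, so
total-ion or class-specific extracted-ion traces become intensity-versus-
temperature curves. Peak temperatures summarize thermal stability; signal
above ~650 °C flags either inorganic carbonates (CO2-dominated, m/z 44) or
highly stable organic matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError
from .spectra_io import Run, Spectrum
from .deconvolution import run_matrix

#: m/z channel conventionally tracked for CO2.
CO2_MZ = 44


@dataclass
class TemperatureProgram:
    """Linear furnace ramp with an initial isothermal hold."""

    start_temp: float = 100.0   # °C
    hold: float = 1.0           # minutes at start_temp
    ramp_rate: float = 10.0     # °C/min
    end_temp: float = 900.0     # °C

    def __post_init__(self) -> None:
        if self.end_temp <= self.start_temp:
            raise ParameterError("end_temp must exceed start_temp")
        if self.ramp_rate <= 0:
            raise ParameterError("ramp_rate must be > 0")
        if self.hold < 0:
            raise ParameterError("hold must be >= 0")

    @property
    def ramp_duration(self) -> float:
        """Minutes from start of run to reaching end_temp."""
        return self.hold + (self.end_temp - self.start_temp) / self.ramp_rate


def time_to_temp(t: float | np.ndarray, prog: TemperatureProgram) -> float | np.ndarray:
    """Furnace temperature (°C) at run time ``t`` (minutes).

    Piecewise linear: start_temp during the hold, then ramping at
    ramp_rate, capped at end_temp. Vectorized over array input.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("time must be >= 0")
    temp = np.where(
        arr <= prog.hold,
        prog.start_temp,
        prog.start_temp + prog.ramp_rate * (arr - prog.hold),
    )
    temp = np.minimum(temp, prog.end_temp)
    return float(temp) if np.isscalar(t) else temp


def temp_to_time(temp: float, prog: TemperatureProgram) -> float:
    """Inverse of :func:`time_to_temp` within the ramp (minutes)."""
    if not prog.start_temp <= temp <= prog.end_temp:
        raise ParameterError(
            f"temperature {temp} outside program range "
            f"[{prog.start_temp}, {prog.end_temp}]"
        )
    if temp == prog.start_temp:
        return prog.hold
    return prog.hold + (temp - prog.start_temp) / prog.ramp_rate


@dataclass
class EGACurve:
    """Intensity as a function of furnace temperature for one channel."""

    temps: np.ndarray            # °C, ascending
    intensity: np.ndarray        # counts
    channel: str | tuple[int, ...] = "TIC"

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.temps) != len(self.intensity):
            raise ParameterError("temps and intensity must have equal length")
        if np.any(np.diff(self.temps) < 0):
            raise ParameterError("temperatures must be ascending")

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def bin_width(self) -> float:
        """Median temperature step between scans (°C)."""
        if len(self.temps) < 2:
            return 0.0
        steps = np.diff(self.temps)
        return float(np.median(steps[steps > 0])) if (steps > 0).any() else 0.0


def ega_curve(
    run: Run,
    prog: TemperatureProgram,
    channel: str | Sequence[int] = "TIC",
    smooth_window: int = 5,
) -> EGACurve:
    """Build a TIC or class-XIC thermal profile from an EGA run.

    ``channel`` is either "TIC" (sum over all m/z bins) or a list of
    nominal m/z values whose traces are summed — e.g. m/z 105 for the
    lignin marker acetophenone, or {94, 107, 108} for the phenol series.
    A centered moving average of ``smooth_window`` scans (default 5)
    smooths the coarse 2 s scan sampling; pass 1 to disable.
    """
    if run.mode != "ega":
        raise ParameterError("ega_curve requires a run in 'ega' mode")
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")
    X, rts, bins = run_matrix(run)
    if isinstance(channel, str):
        if channel.upper() != "TIC":
            raise ParameterError(f"unknown channel {channel!r}")
        trace = X.sum(axis=1)
        chan: str | tuple[int, ...] = "TIC"
    else:
        mzs = [int(m) for m in channel]
        if not mzs:
            raise ParameterError("channel m/z list must be non-empty")
        lo = int(bins[0])
        cols = []
        for m in mzs:
            j = m - lo
            if not 0 <= j < len(bins):
                raise ParameterError(
                    f"channel m/z {m} outside the EGA scan range "
                    f"[{bins[0]}, {bins[-1]}]"
                )
            cols.append(j)
        trace = X[:, cols].sum(axis=1)
        chan = tuple(mzs)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.r_[np.full(pad, trace[0]), trace, np.full(pad, trace[-1])]
        trace = np.convolve(padded, kernel, mode="valid")[: len(rts)]
    temps = time_to_temp(rts, prog)
    return EGACurve(np.asarray(temps), trace, chan)


def peak_temperatures(
    curve: EGACurve, min_prominence: float = 0.1
) -> list[float]:
    """Temperatures of local maxima, largest intensity first.

    ``min_prominence`` is a fraction of the curve maximum (default 0.1);
    a flat curve yields an empty list. The first element is the global
    peak temperature — the temperature at which signal intensity is
    highest.
    """
    if not 0 < min_prominence <= 1:
        raise ParameterError("min_prominence must be in (0, 1]")
    y = curve.intensity
    if len(y) < 3 or np.ptp(y) == 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * y.max())
    # an apex at the trace boundary has no flanking minima; include the
    # global maximum even when find_peaks misses it at an endpoint
    if len(idx) == 0:
        return []
    order = sorted(idx, key=lambda i: (-y[i], i))
    return [float(curve.temps[i]) for i in order]


@dataclass
class HighTempReport:
    """Assessment of signal above the inorganic-carbon cutoff temperature."""

    flagged: bool                 # any reported peak above cutoff
    cutoff: float                 # °C
    fraction_above: float         # share of total signal above cutoff
    co2_dominated: bool | None    # CO2 share > co2_ratio above cutoff
    interpretation: str           # "IC-consistent" | "stable-OM-consistent" | "none"


def high_temp_flag(
    curve: EGACurve,
    co2_curve: EGACurve,
    cutoff: float = 650.0,
    co2_ratio: float = 0.5,
) -> HighTempReport:
    """Flag high-temperature signal and judge its likely carbon source.

    A peak temperature above ``cutoff`` (default 650 °C) may indicate
    inorganic carbonates or highly stable organic matter. When flagged,
    the CO2 (m/z 44) share of the summed channel intensity in the
    above-cutoff region decides between the two readings: share >
    ``co2_ratio`` is carbonate-like (IC-consistent), otherwise the signal
    reads as thermally stable organic matter.
    """
    peaks = peak_temperatures(curve)
    flagged = any(t > cutoff for t in peaks)
    total = float(curve.intensity.sum())
    above = curve.temps > cutoff
    fraction_above = (
        float(curve.intensity[above].sum()) / total if total > 0 else 0.0
    )
    co2_dominated: bool | None = None
    interpretation = "none"
    if flagged:
        co2_above = co2_curve.temps > cutoff
        chan_sum = float(curve.intensity[above].sum())
        co2_sum = float(co2_curve.intensity[co2_above].sum())
        co2_dominated = chan_sum > 0 and co2_sum / chan_sum > co2_ratio
        interpretation = (
            "IC-consistent" if co2_dominated else "stable-OM-consistent"
        )
    return HighTempReport(flagged, cutoff, fraction_above, co2_dominated,
                          interpretation)


def spectrum_at_peak(
    run: Run, prog: TemperatureProgram, temp: float, window_scans: int = 1
) -> Spectrum:
    """Mean spectrum in a ±``window_scans`` window around a peak temperature."""
    if window_scans < 0:
        raise ParameterError("window_scans must be >= 0")
    temps = np.asarray(time_to_temp(run.rts, prog))
    center = int(np.argmin(np.abs(temps - temp)))
    lo = max(0, center - window_scans)
    hi = min(len(run.scans), center + window_scans + 1)
    X, _, bins = run_matrix(run)
    mean_vec = X[lo:hi].mean(axis=0)
    nz = mean_vec > 0
    if not nz.any():
        raise ParameterError(f"no signal near {temp} °C")
    return Spectrum(bins[nz].astype(float), mean_vec[nz],
                    rt=float(run.rts[center]))


def curve_table(curves: dict[str, EGACurve]) -> pd.DataFrame:
    """Wide table temp_C x named channels (TIC, class XICs)."""
    out: dict[str, np.ndarray] = {}
    temps = None
    for name, c in curves.items():
        if temps is None:
            temps = c.temps
        out[name] = c.intensity
    df = pd.DataFrame(out)
    df.insert(0, "temp_C", temps)
    return df


def write_curve(curve: EGACurve, path: str | Path) -> None:
    pd.DataFrame({"temp_C": curve.temps, "intensity": curve.intensity}).to_csv(
        path, index=False
    )


def read_class_xic_config(path: str | Path) -> dict[str, list[int]]:
    """Read the class -> m/z list table (columns: class, mz; one row per m/z)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "class" not in cols or "mz" not in cols:
        raise ParameterError(
            f"class-XIC config {path} needs 'class' and 'mz' columns"
        )
    out: dict[str, list[int]] = {}
    for cls, mz in df[[cols["class"], cols["mz"]]].itertuples(index=False):
        out.setdefault(str(cls).strip(), []).append(int(mz))
    return out
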