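"""Evolved-gas analysis: thermal profiles and the high-temperature flag.

Simulates an EGA run (100 C hold, then 10 C/min to 900 C) with an organic
component evolving at 455 C and a carbonate-like CO2 release at 723 C,
then extracts the TIC, per-class XICs, peak temperatures and the >650 C
inorganic-carbon assessment.
"""

import numpy as np

from pyrosom import ega_curve, high_temp_flag, peak_temperatures, time_to_temp
from pyrosom.ega import CO2_MZ, TemperatureProgram
from pyrosom.spectra_io import Run, Spectrum

prog = TemperatureProgram()  # 100 C, 1 min hold, 10 C/min, 900 C
times = np.arange(0.0, prog.ramp_duration + 1.0, 2.0 / 60.0)  # 2 s scans
scans = []
for t in times:
    T = time_to_temp(t, prog)
    organic = 1e6 * np.exp(-((T - 455.0) ** 2) / (2 * 25.0**2))
    carbonate = 8e5 * np.exp(-((T - 723.0) ** 2) / (2 * 25.0**2))
    scans.append(Spectrum(
        np.array([44.0, 94.0, 105.0]),
        np.array([1 + carbonate, 1 + 0.5 * organic, 1 + organic]),
        rt=float(t)))
run = Run(scans, mode="ega", scan_interval=2.0)

tic = ega_curve(run, prog, "TIC")
lignin_xic = ega_curve(run, prog, [105])     # acetophenone marker
phenol_xic = ega_curve(run, prog, [94])      # phenol marker

print("peak temperatures (C), largest first:")
print(f"  TIC:    {[round(t, 1) for t in peak_temperatures(tic)]}")
print(f"  lignin: {[round(t, 1) for t in peak_temperatures(lignin_xic)]}")
print(f"  phenol: {[round(t, 1) for t in peak_temperatures(phenol_xic)]}")

co2 = ega_curve(run, prog, [CO2_MZ])
rep = high_temp_flag(tic, co2, cutoff=650.0)
print(f"\nsignal above 650 C: {100 * rep.fraction_above:.1f}% of TIC; "
      f"flagged: {rep.flagged}; reading: {rep.interpretation}")

# The organic component peaks at 455 C in every channel carrying it; the
# 723 C CO2-dominated peak trips the flag and reads as inorganic carbonate.
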