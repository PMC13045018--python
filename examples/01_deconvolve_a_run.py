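"""Deconvolute a synthetic pyrolysis run and compare against planted truth.

Simulates 12 pyrolysates (3 of them forced into co-eluting pairs closer
than the 0.05 min tolerance), builds extracted-ion chromatograms, detects
peaks, and resolves components with MCR-ALS.
"""

from pyrosom import cosine, deconvolve, gen_compound_set, gen_run

compounds = gen_compound_set(12, seed=1)
noise_sd = 0.01 * min(c.height for c in compounds)
run, truth = gen_run(compounds, noise_sd=noise_sd, co_elute_pairs=3, seed=1)

features = deconvolve(run, sample_id="demo")
print(f"{len(run)} scans -> {len(features)} deconvoluted features "
      f"({len(truth.co_eluting)} planted co-eluting pairs)")

for c in truth.compounds:
    best = max(features, key=lambda f: cosine(f.spectrum, c.spectrum))
    sim = cosine(best.spectrum, c.spectrum)
    print(f"  {c.name:<18} planted rt {c.rt:5.3f} min -> "
          f"feature rt {best.rt:5.3f}, spectral cosine {sim:.3f}")

# A cosine near 1 means the resolved component spectrum matches the planted
# compound; rt agreement within one scan (0.005 min) shows apex recovery.
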