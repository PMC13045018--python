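# Methods

This note documents the models and procedures implemented in `pyrosom`,
the parameter defaults and why they hold, the numerical choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate about real instrument data.

## Data model

An EI fragmentation spectrum is a stick spectrum: strictly ascending m/z
values with non-negative intensities, normalized so the base peak is 999
(the convention of EI library formats). Retention times are minutes
everywhere; files reporting seconds are converted on load. Acquisition
windows are m/z 29–850 for pyrolysis-GC/MS runs and 29–650 for EGA runs,
and peaks outside the window are dropped at load time. All spectral
comparisons happen on the unit-mass (integer) grid: EI quadrupole data and
the common reference libraries are nominal-mass, so finer binning would
only split matching fragments apart. Profile-mode scans are centroided by
local-maximum picking on load.

The mzML reader is a minimal, self-contained MS1 parser (namespace-aware
XML walk; 32/64-bit little-endian arrays, zlib or uncompressed); the
writer emits uncompressed 64-bit mzML 1.1.0. MSP is parsed with strict
record validation — a record whose peak list disagrees with its
`Num Peaks:` declaration is an error naming that record — and MGF goes
through pyteomics. Compound names are matched case-insensitively with
whitespace collapsed and trailing CAS-style registry suffixes stripped,
since library hit strings vary in all three.

## Deconvolution (MCR-ALS)

Extracted-ion chromatograms exist for every integer m/z bin whose trace
reaches the intensity threshold (default 1e5 counts) at least once; the
threshold gates existence, not points, so sub-threshold parts of a kept
trace are retained. Peaks are local maxima with height ≥ 1e5 counts and
signal-to-noise ≥ 5, where the noise sigma is `1.4826 · MAD(Δy) / √2` —
the median absolute deviation of the trace's first differences, which is
insensitive to the peaks themselves; 1.4826 makes the MAD consistent with
a Gaussian sigma and √2 removes the variance doubling of differencing.
Peak bounds are the nearest flanking minima.

Peak apexes are clustered twice by single-linkage on retention time:

- gaps > `rt_tol` (default 0.05 min) delimit independent windows;
- within a window, gaps > `apex_gap` (default 0.01 min — two scan
  intervals at the default 0.3 s scan time) delimit components. Fragments
  of one compound apex within a scan of each other; distinct co-eluting
  compounds sit several scans apart, so the finer clustering counts
  components down to ~0.02 min separations.

Adjacent windows are clipped at the midpoint between their apex groups so
one window's matrix never contains a neighbor's peak region. Each window's
scans × m/z matrix is factorized as X ≈ C·Sᵀ with both factors
non-negative, by alternating exact non-negative least squares (each
half-step is a set of NNLS solves, so the residual is monotone
non-increasing). S is seeded from the raw spectra at each component's apex
scan; iteration stops when the relative residual improves by < 1e-6 or at
200 iterations. Because a fragment bin shared between two co-eluting
compounds can bridge their apex groups into one cluster (and ALS can
occasionally settle in a local minimum), the component count is escalated
while the relative residual exceeds 1% (at most +2 components, each seeded
from the worst-fit scan); this residual-driven rank selection replaces the
unknown component-count rule of the GUI resolver the workflow replaces.

A component's spectrum is its S column normalized to base peak 999; its
height is the apex of its base-peak elution trace (`max(C·maxS)`), the
scale on which the minimum-height filter applies, and its area is the
trapezoidal integral of that trace in counts·min.

## Alignment

Features from different samples merge when
`w_rt · max(0, 1 − |ΔRT|/rt_tol) + (1 − w_rt) · cos(s₁, s₂)` reaches the
threshold (default 0.7), with `w_rt = 0.5` and `rt_tol = 0.05` min. Only
the threshold is externally fixed; the even RT/spectral weighting mirrors
the blended score structure of published GC aligners and is exposed as a
parameter. Merging is greedy best-pair-first with deterministic
tie-breaking (lower mean RT, then sample ids); a merge is accepted only if
the two groups share no sample, and features never merged end up as
singleton groups, so the output partitions the input. Consensus spectra
are the height-weighted mean of base-peak-normalized member spectra.

## Annotation and classification

Library matching uses plain cosine on raw intensities on the unit-mass
grid — transparent and oracle-checkable; optional intensity- and
m/z-power weightings (NIST-style) are available but default off. A node
takes its best-scoring entry when the score reaches `min_cosine` (0.7);
ties are broken by library order and flagged. Class assignment is a pure
lookup into the class table; annotated-but-unlisted compounds and
unannotated nodes are labelled "unclassified" explicitly, and the
operation is idempotent.

## Molecular networking

All pairwise cosines are computed; candidate edges need cosine ≥ 0.7, and
an edge survives only if each endpoint ranks the other within its top 10
candidates (mutual TopK) — the only pruning rule that actually guarantees
the "maximum neighbors per node" reading of TopK. Nodes without surviving
edges are singletons and are excluded from cluster (connected-component)
output. Class propagation is a single pass from originally-annotated nodes
only: an unclassified node takes the class of its highest-cosine annotated
neighbor (ties: larger total abundance, then smaller node id), provenance
is recorded as "library" vs "propagated", and chained propagation through
freshly propagated labels is available behind a flag but off by default —
single-pass keeps every inferred label one edge from measured evidence.

## Ecological statistics

Class relative abundances are shares of summed feature heights per sample
(heights, not areas, are the default because heights are what the detector
thresholds; an area switch exists). They are detector-response shares, not
carbon-mass shares. Diversity uses the natural-log Shannon index and the
Gini–Simpson form 1 − Σp² (on this scale larger = more diverse, which is
the scale on which a value like 0.87 can be called "low"). Diversity is
computed over compounds by default, classes optionally.

PERMANOVA decomposes the squared-distance sum: `SS_total = Σ_{i<j} d²/n`,
`SS_within` summed per group with its own size, pseudo-F =
`(SS_between/(a−1)) / (SS_within/(n−a))`, and p from whole-label
permutations with the +1 correction, seeded for reproducibility. Labels
permute freely (no strata), matching the default of the standard
distance-based procedure. Hierarchical clustering applies ln(x+1) (the
log transform must handle zeros; the base is a free choice that only
rescales distances) and average linkage on Bray–Curtis distances via
scipy; the dendrogram exports to Newick. Pearson correlation between
ecosystem profiles is computed on the union of compounds with absences as
zero, length ≥ 3, and errors on zero variance.

## EGA profiling

Scan time maps to furnace temperature piecewise-linearly: `start_temp`
during the hold, then `start_temp + rate·(t − hold)` capped at `end_temp`
(defaults 100 °C, 1 min, 10 °C/min, 900 °C). Curves are per-scan sums over
a channel (all bins for TIC; a class's marker m/z list for XICs — e.g.
m/z 105 for the lignin marker, {94, 107, 108} for the phenol series), with
a centered 5-scan moving average by default because 2 s scans sample the
ramp coarsely (one scan ≈ 0.33 °C). Peak temperatures are local maxima
with prominence ≥ 10% of the curve maximum, largest first. Signal above
the 650 °C cutoff is flagged, and the CO₂ (m/z 44) share of the
above-cutoff channel signal decides between carbonate-like
("IC-consistent", share > 0.5) and thermally stable organic matter
("stable-OM-consistent"); the 0.5 dominance ratio operationalizes a
qualitative acid-treatment argument and is exposed in the configuration.

## Synthetic data: what it emulates, and what it does not

The generator emulates: Gaussian elution peaks (sd 0.02 min, chosen so the
0.05 min tolerance is meaningfully stressed by planted co-elution at
0.025–0.05 min separations), EI stick spectra organized into structural
families (families share their dominant fragments, so within-family cosine
exceeds 0.7 and cross-family cosine stays below 0.5 in ≥ 95% of draws —
the regime molecular networking assumes), additive Gaussian detector noise
over a flat baseline, log-normal abundances (σ = 1) for realistic
rank-abundance curves, and multi-ecosystem designs with a shared core,
single-ecosystem tails and a wetland-exclusive compound set whose count is
exact by construction. All generators are deterministic under a seed.

It does not emulate: retention-time drift between runs (no warping is
implemented, so none is planted), peak tailing or fronting, mass-accuracy
errors, detector saturation, isotope patterns, or chemically realistic
fragmentation. Passing benchmarks therefore demonstrate the correctness of
the algorithms under the stated noise model — not instrument-grade
robustness; on real data the alignment tolerance and thresholds carry the
burden these artifacts create.

Benchmark problem sizes (20-compound runs with 5 co-eluting pairs, 100
noisy annotation queries, 600–1000-node networks, 500 PERMANOVA null
simulations at n = 12 with 199 permutations, 5 ecosystems × 3 replicates)
were chosen so the full suite and the acceptance script each run in well
under a minute while every rate is estimated from enough trials to be
stable across seeds.

## Known limitations

- Unit-mass binning discards any high-resolution information present in
  the source data.
- The greedy aligner does not correct retention drift; runs needing
  warping should be aligned upstream.
- ALS component-count escalation can split a compound with a strongly
  asymmetric elution profile into two features; alignment usually
  re-merges them, but duplicate features are possible.
- PERMANOVA assumes exchangeable samples under the null; nested or
  repeated-measures designs need strata, which are not implemented.
- The IC/stable-OM reading of high-temperature signal is a heuristic on
  CO₂ dominance, not a carbonate measurement.
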