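# Methods

## Signal model

The forward model is a CPMG multi-echo spin-echo train: excitation about
x (nominal 90°), refocusing about y (nominal 125°), echo spacing 5.9 ms,
10 echoes, TR 2057 ms. Both flip angles are scaled by the local transmit
field B1+ (a dimensionless fraction, 1.00 = nominal), so B1+
inhomogeneity and refocusing imperfection share one parameter.

Echo amplitudes are computed with the extended phase graph (EPG)
recursion over configuration states F+(k), F−(k), Z(k). Ideal crusher
gradients are assumed: one dephasing unit per half echo-spacing, and no
transverse coherence survives outside the tracked orders. The state table
holds 2·n_echoes + 2 orders, enough that no pathway of the train is ever
shifted out of range (unrefocused magnetization gains two orders per
period). T2 decay acts on transverse states and T1 relaxation (with
regrowth toward equilibrium on Z0) on longitudinal states each half
period. Echoes are read as |F+(0)|. Because matching is performed on
L2-normalized curves, the absolute signal scale — proton density, coil
sensitivity, inter-TR steady state — cancels; TR enters only through the
(negligible) T1 term, so no steady-state modelling across repetitions is
attempted (train length 59 ms ≪ TR 2057 ms).

Hard pulses are the default. A `shaped` option splits the slice into
sub-slices (default 15) whose flip angles follow a tabulated profile and
sums the complex sub-slice signals before taking the magnitude; since
vendor pulse shapes are not published, this is a configurable
approximation, and the ±40% B1+ search range absorbs residual profile
error.

### Verification oracle

An isochromat Bloch simulator of the same train serves as the independent
check: N spins with equally spaced crusher phases over 2π, evolved with
3×3 Cartesian rotation matrices (precession about z, RF about x/y) and
per-half-period relaxation. An equally spaced phase grid is exact
quadrature for every configuration order below N, so the oracle agrees
with EPG to machine precision once N exceeds the state order (~22); the
test suite requires 1e-6 relative agreement over a 5×5×3 grid of
(T2, B1+, refocusing angle) and observes ~1e-15.

## Dictionary and matching

The dictionary holds one L2-normalized curve ("atom") per (T2, B1+) grid
pair: T2 ∈ {1, …, 300} ms, B1+ ∈ {0.60, …, 1.40} step 0.01, T1 fixed at
1000 ms — 24,300 atoms of length 10. Unit normalization makes
maximum-dot-product matching equal maximum cosine similarity, so matching
is invariant to per-pixel scale. Grid construction refuses ranges not
divisible by the step (no silent truncation); dictionaries are
deterministic and can be cached/persisted as `.npz` keyed by a SHA-256
content hash of grid + sequence parameters. A `skip_first_echo` switch
drops echo 1 from atoms and pixels alike (a common MESE practice); the
default uses all 10 echoes.

Matching is exhaustive: for each pixel the best atom is found by a
running-maximum scan (numba-compiled) equivalent to
`argmax(atoms @ pixel)` but without materializing the 24,300 × n_pixels
score matrix. Scores are accumulated in double precision — adjacent
long-T2 atoms are nearly collinear (1 − cos ≈ 2e-7 at T2 ≈ 300 ms), so
single precision can misrank them. Ties break toward the smallest T2,
then the B1+ closest to 1.00, encoded in the atom ordering so that the
first maximum wins. Zero-norm pixels are marked invalid (NaN plus a False
validity mask), never raised. No minimum-score threshold and no spatial
regularization are applied: estimation is strictly pixel-wise.

The mono-exponential baseline is an ordinary log-linear least-squares fit
over the strictly positive samples, returning NaN for non-decaying
series. On 125°-refocused trains it overestimates T2 by ~7–11 ms in the
cartilage band (30–60 ms) where dictionary matching is exact up to grid
quantization; the test suite asserts this ordering point-wise.

Monte-Carlo calibration at first-echo SNR 50 (truth 43 ms): with B1+
known, the matched T2 lies within ±2 ms in ≥95% of draws; joint (T2, B1+)
estimation admits a T2–B1 ambiguity that fattens the error tail to
~86–93% within ±2 ms. Both calibrated facts are asserted. Region means
are much better behaved than single pixels: at SNR 50 the median
per-region error for regions of ≥200 pixels is ~0.2 ms.

## Regions, fluid exclusion, statistics

Sixteen base sections (LF/LT/MF/MT × anterior/central/posterior, plus
LPpf, LFpf, Pt, Ft) are encoded as integer labels; reported aggregates
are pixel unions (LF, LT, MF, MT plates; LatC = LF∪LT; MedC = MF∪MT;
LPF = LPpf∪LFpf; TrPF = Pt∪Ft; T2Tot = all base sections pooled once).
The full reporting set has 25 regions; aggregates whose member sections
are absent from a custom scheme are dropped (a condyle-only scheme yields
18). Aggregates pool pixels rather than averaging section means — this
matters whenever sections differ in size, and is asserted by test.

Synovial fluid is removed by the strict rule T2 > 100 ms (a pixel at
exactly 100 ms is kept). The filter is idempotent and applied before any
region statistic. Region SD uses the sample form (n−1), the default of
the statistics packages such studies use; single-pixel regions report SD
as missing. Each of the three slices of a knee is treated as an
independent sample (no within-knee averaging), matching the study design
of 19 knees × 3 slices = 57 samples; the statistical dependence this
induces is replicated deliberately, not corrected.

### Recovery metrics

Deltas are signed (negative = T2 loss): Δrun = T2_21k − T2_rest,
Δctrl = T2_control − T2_rest, with percent versions relative to rest.
Group rows use a mixed convention mirroring the study tables: delta
columns are mean ± SD over per-sample values, while the group PRI is
computed from the group-mean T2 triplet — this is the convention that
reproduces the published PRI values from the published mean triplets
(verified row by row; interval analysis over the one-decimal rounding of
the printed means covers the rows whose PRI was evidently computed from
unrounded means). PRI is undefined (missing, with a warning) when rest
and 21k coincide. Reports round ms, percent and PRI to one decimal;
intermediate tables keep full precision.

### Longitudinal battery

One-way within-subject ANOVA across the three timepoints: Mauchly's W on
the orthonormal-contrast covariance with the standard chi-square
approximation; Greenhouse–Geisser epsilon from the eigenvalues of that
covariance and Huynh–Feldt epsilon clipped at 1. When Mauchly rejects at
0.05, GG is applied if ε_GG < 0.75, else HF (the conventional rule).
Planned paired comparisons are exactly rest-vs-21k and rest-vs-control
with Bonferroni factor 2 (a switch enables all three pairs with factor
3); adjusted p values are capped at 1. The normality screen per column is
a Lilliefors-corrected Kolmogorov–Smirnov test (naive KS with plug-in
estimates would be anti-conservative) plus |skewness| < 2 and |excess
kurtosis| < 7 (George & Mallery bounds, configurable); any failure routes
the block to a tie-corrected Friedman test with Wilcoxon signed-rank
follow-ups. The ANOVA chain is cross-checked against pingouin to 1e-8,
and the combined decision procedure holds its type-I error at ≈0.045–0.05
(≤ 0.07 asserted) over 1,000 null blocks of n = 19.

## Synthetic phantom

The phantom is schematic by design — the pipeline is geometry-agnostic,
so anatomical realism buys nothing testable. Each 96×96 slice (default)
contains two femoral arc bands split into thirds by arc angle, two tibial
bands split by column, four patellofemoral patches, and thin fluid rims
above the femoral cartilage. Default section counts per slice range from
~80 (patellofemoral patches) to ~1,560 pooled cartilage pixels; plates
and condyles exceed the 200-pixel level at which ±1 ms region recovery is
asserted.

Ground-truth baselines use the published rest-column means per plate
(LF 45.0, LT 36.4, MF 45.9, MT 40.8 ms; patellofemoral sections 41.4,
47.0, 43.4, 44.6 ms); fluid T2 is uniform in 120–250 ms, safely above the
100 ms cutoff. Timepoint effects are per-section percent changes; the
default is the study-scale global −2% at 21k with complete recovery at
control. An `on_grid` switch rounds truths to the 1 ms dictionary grid so
the zero-noise closed loop is bit-exact. B1+ is constant 1.0 by default,
or a smooth radial polynomial within a configurable range inside
[0.60, 1.40]. Noise is Rician (two Gaussian channels on the complex
signal before magnitude) or Gaussian, with σ = mean first-echo cartilage
amplitude / SNR, default SNR 50. Proton density is constant (matching is
scale-invariant).

`make_study` assembles the full design: 11 right-knee-dominant
participants (4 female — the study's sex ratio, scaled for other n),
bilateral, three slices per knee, three timepoints, and a deterministic
dropout of 3 knees emulating motion-artefact exclusion — 19 knees,
57 samples. Noise streams are spawned per (participant, knee, timepoint)
from the study seed, so dropout never shifts the noise of remaining
knees. What the phantom does *not* emulate: anatomical shape variation,
partial-volume and multi-component T2, magic-angle orientation effects,
B0 inhomogeneity, and between-subject covariance structure beyond a
shared truth map — so passing tests demonstrate pipeline correctness and
statistical calibration, not in-vivo accuracy.

## Problem sizes and numerical choices

The default test and acceptance runs use the full 24,300-atom dictionary
and the full 57-sample study; Monte-Carlo replication counts are kept
moderate (8–25 seeds for calibration medians, 200 draws for pixel-level
rates, 1,000 null blocks for type-I error) as the package's own choice of
problem size. Matching cost is ~84 µs per pixel on one core; a full
3-timepoint study fit is ~20 s. Degenerate inputs are defined
throughout: empty masks yield all-invalid maps; regions emptied by the
fluid filter are dropped with a logged warning; zero-variance columns
fail the normality screen with an explicit reason; constant blocks give
F = 0 with intact degrees of freedom and pairwise p = 1.

## Known limitations

- The dictionary's 1 ms T2 step bounds single-pixel accuracy; no
  interpolation between atoms is attempted.
- Joint (T2, B1+) estimation is weakly identified from 10 echoes at a
  single refocusing angle; the ±2 ms pixel-level guarantee holds only
  with B1+ known, while region means remain accurate (see calibration
  above).
- Slices and knees are treated as independent samples, inheriting the
  study design's pseudo-replication rather than modelling within-knee
  correlation.
- The shaped-pulse option approximates, but cannot reproduce, unpublished
  vendor pulse profiles.
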