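# emct2

Dictionary-matching (echo-modulation-curve) T2 relaxometry of knee
articular cartilage, with a three-timepoint exercise/recovery analysis
pipeline and a fully synthetic knee phantom generator.

## The problem

T2 relaxation time of knee articular cartilage (KAC) tracks water content
and collagen organization, and transiently drops after long-distance
running as cartilage dehydrates under load. Quantifying that drop — and
whether T2 returns to baseline within a recovery week — requires accurate
per-pixel T2 estimates from multi-echo spin-echo (MESE) images.

Conventional mono-exponential fitting of the MESE echo decay is biased:
with non-180° refocusing pulses (here 125°), stimulated-echo pathways make
the decay non-exponential, and the naive fit systematically overestimates
T2. The echo-modulation-curve (EMC) approach instead forward-simulates the
full acquisition with the extended phase graph (EPG) formalism for every
(T2, B1+) combination on a grid — T2 from 1 to 300 ms in 1 ms steps, the
transmit field B1+ from 60% to 140% in 1% increments, T1 fixed at
1000 ms — and assigns each pixel the grid pair whose L2-normalized curve
has the maximum dot product with the pixel's normalized echo series.

Downstream, cartilage is divided into WORMS-derived regions (four condyle
plates × anterior/central/posterior, patellofemoral sections, their
pooled aggregates and a grand total — 25 regions), synovial fluid is
excluded by removing pixels with T2 > 100 ms, and per-region mean T2 is
tracked over three timepoints: **rest**, immediately **post-run (21k)**,
and a one-week **control**. Recovery is summarized by the Proportional
Recovery Index

```
PRI = (T2_control − T2_21k) / (T2_rest − T2_21k)
```

(1 = complete recovery, <1 incomplete, >1 overcompensation, <0 continued
deterioration), and inference uses repeated-measures ANOVA with Mauchly's
sphericity test, Greenhouse–Geisser/Huynh–Feldt corrections and
Bonferroni planned comparisons, falling back to Friedman tests when a
Lilliefors/skewness/kurtosis normality screen fails.

Because no imaging data are distributed with the package, a synthetic
phantom module renders schematic three-slice knees (curved femoral bands,
tibial plateaus, patellofemoral patches, fluid rims) through the same EPG
forward model with Rician noise, so the entire pipeline is testable end to
end, including recovery of configured timepoint effects.

## Worked example

```python
import numpy as np
from emct2 import (SequenceParams, RelaxationParams, B1Scale, simulate_emc,
                   build_grid, build_dictionary, match_pixel,
                   fit_monoexponential, echo_train, TimepointTriplet,
                   compute_pri)

seq = SequenceParams()          # TR 2057 ms, 10 echoes @ 5.9 ms, 90°/125°
curve = simulate_emc(RelaxationParams(t2=43.0), B1Scale(0.95), seq)
print("echo amplitudes:", np.round(curve.amplitudes, 4))

dictionary = build_dictionary(build_grid(), seq)  # 24,300 atoms
rng = np.random.default_rng(0)
noisy = np.abs(curve.amplitudes + rng.normal(0, curve.amplitudes[0] / 50, 10))
t2, b1, score = match_pixel(noisy, dictionary)
print(f"matched: T2 = {t2:.0f} ms, B1+ = {b1:.2f}, score = {score:.4f}")
print(f"mono-exponential fit: {fit_monoexponential(noisy, echo_train(seq)):.1f} ms")

pri = compute_pri(TimepointTriplet(t2_rest=42.4, t2_21k=40.7, t2_control=40.5))
print(f"PRI = {pri:.3f}")
```

prints

```
echo amplitudes: [0.6436 0.7475 0.5711 0.5323 0.4756 0.4214 0.3604 0.3425 0.2833 0.265 ]
matched: T2 = 43 ms, B1+ = 0.95, score = 0.9998
mono-exponential fit: 50.8 ms
PRI = -0.118
```

Note the second echo exceeding the first (a stimulated-echo signature),
the exact T2/B1+ recovery by dictionary matching at SNR 50, and the ~8 ms
overestimate by the mono-exponential fit on the same data. The PRI of
−0.118 (≈ −0.1) says that in this compartment T2 kept falling after the
run instead of recovering.

A command-line interface mirrors the library (`emct2 build-dict`, `fit`,
`roi-stats`, `recovery`, `stats`, `simulate`, `run-study`); `run-study`
takes a YAML config and writes the four report tables (global /
laterality / sex, by compartment, by section, compartment × subgroup)
plus a JSON provenance sidecar.

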