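# radiocell

Single-cell multimodal radiography analysis: from raw-style microscope images
to a per-cell table of **dry mass**, **cell-cycle phase** and
**decay-corrected [18F]FDG counts/min**, with the statistical analyses that
relate radiotracer uptake to cell mass and cycle phase.

The package is aimed at researchers combining quantitative phase microscopy
(QPM), FUCCI two-channel fluorescence, and radioluminescence microscopy (RLM)
on the same field of view — for example HeLa-FUCCI cells labelled with
[18F]fluorodeoxyglucose growing on a CdWO4 scintillator. Because raw
single-cell radiography data of this kind are not publicly deposited, the
package ships a first-class synthetic-data simulator with known ground truth,
so every stage (and the whole chain) is verifiable by parameter recovery.

## What it computes

**Dry mass from phase.** An off-axis interferogram is demodulated in the
spatial-frequency domain (sideband selection → baseband → 2D unwrap →
background surface removal), giving the optical phase map Φ(x, y). The dry
mass of a cell follows from

```
m = λ / (2πα) ∬ Φ(x, y) dx dy
```

with λ = 0.633 µm (He-Ne) and α = 0.18 mL/g ≡ 0.18 µm³/pg the specific
refraction increment; the integral runs over the cell area segmented from the
phase image itself (1 rad over 100 µm² ↔ 55.97 pg).

**Cycle phase from FUCCI.** Each channel is flat-fielded against its own
empty-field background, offset-subtracted and noise-thresholded; the green
and red sums over the cell area give the phase: red-only → G1, green-only →
S/G2/M, both → G1/S, neither → M/G1.

**Counts/min from RLM.** Frames are dark-corrected, then scintillation events
are detected (binary threshold 700, h-maxima suppression h = 100, sharpness
k-space radius 20, max track length 10 binned px = 50 µm). Only *short*
ionization tracks — positrons crossing the crystal near-perpendicular, which
localize the emitter — are counted at their intensity-weighted centre of
gravity; long streaks, diffuse gamma glows and direct sensor hits are
discarded. Cell boundaries are dilated by one PSF sigma (12.5 µm, from the
~30 µm FWHM resolution) before integrating counts; cells whose dilated
boundaries merge are discarded. Counts are divided by live time and
multiplied by the fluorine-18 decay factor `2^(Δt / 110 min)` referred to
the tracer calibration time.

**Statistics.** Median/IQR summaries per cycle-phase group, two-tailed
Mann–Whitney–Wilcoxon, one-way ANOVA, and robust regression of counts/min on
dry mass by iteratively reweighted least squares with Huber weights
(c = 1.345, MAD scale), reporting adjusted R².

## Worked example

```sh
radiocell simulate --n-cells 26 --seed 1 --frames 3000 --out demo/ds
radiocell process --in demo/ds --out demo/out
radiocell report --table demo/out/cell_table.csv --out demo/report
```

`process` prints the stage ledger for the simulated field of view:

```json
{
  "cells_segmented": 26,
  "cells_kept": 26,
  "cells_discarded": 0,
  "events_detected": 2205,
  "events_by_class": {"diffuse": 278, "long": 336, "sensor_hit": 4, "short": 1587},
  "events_accepted": 1587
}
```

2205 ionization tracks were detected across 3000 frames; the 1587 short
tracks were counted, the rest rejected by morphology. `cell_table.csv` then
holds one row per kept cell:

```
label,dry_mass_pg,counts_per_min,cycle_phase,green_sum,red_sum,merged,overridden
1,681.517754,55.46024402,G1_S,3282.385846,2425.620827,False,False
2,672.2776861,59.83868433,S_G2_M,4417.904315,0.07471972875,False,False
...
```

and `stats_report.json` the population analysis for this seed: dry-mass
median 517.5 pg, counts/min median 64.9, robust counts-vs-mass fit with
slope 0.228 counts/min/pg (adjusted R² 0.74, P = 1e-08), S/G2/M uptake
1.97× the G1 median (two-tailed Mann–Whitney P = 0.0062). Cells in later
cycle phases carry about twice the tracer signal of G1 cells, and uptake
scales with dry mass — the structure the simulator's defaults encode.

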