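# Methods

## Scope and model

`radiocell` implements a single-field-of-view measurement chain for
multimodal single-cell radiography:

1. **QPM** — off-axis interferogram → phase map → per-cell dry mass via
   m = λ/(2πα)·∬Φ, evaluated as a Riemann sum over mask pixels times pixel
   area (no subpixel boundary weighting).
2. **FUCCI** — two-channel fluorescence → normalized per-cell sums → cycle
   phase by the red-only/green-only/both/neither rule.
3. **RLM** — frame stack → dark correction → per-frame event detection and
   track-morphology filtering → short-track counts image → per-cell,
   decay-corrected counts/min.
4. **stats** — group summaries (median, type-7 linear-interpolation
   quartiles), two-tailed Mann–Whitney–Wilcoxon, one-way ANOVA, Huber-IRLS
   robust regression with adjusted R².

All lengths are µm, masses pg, times s (rates per min where named so). The
coordinate convention is 0-based pixel-centre with the physical origin at the
full-resolution top-left pixel centre; the 8×8-binned pixel (I, J) covers
full-resolution rows [8I, 8I+8) (half-open), on both the 0.625 µm and the
5 µm grids.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| pixel pitch | 0.625 µm | full-resolution sampling; 1024 px → 640 µm FOV |
| RLM binning | 8×8 | 5 µm/px acquisition grid for the frame stack |
| PSF FWHM | 30 µm | scintillation light spread; σ = FWHM/2.355 ≈ 12.74 µm |
| dilation radius | 12.5 µm | one σ added around each cell before count integration |
| λ, α | 0.633 µm, 0.18 µm³/pg | dry-mass conversion constants |
| binary threshold | 700 | event detection intensity cut (camera counts) |
| h value | 100 | prominence of the h-maxima suppression step |
| sharpness | 20 | k-space radius (bins on a 128-px window) of the spectral cut |
| max track length | 10 binned px (50 µm) | long-track rejection |
| exposure | 20 ms | per frame; live time = n_frames × exposure |
| dead time | 32 % | readout gaps; stretches wall clock, not live time |
| half-life | 110 min | fluorine-18; decay factor 2^(Δt/110) |
| Huber c | 1.345 | classical 95%-efficiency tuning constant |
| phase threshold | 0.15 rad | segmentation cut on the leveled phase image |
| min cell area | 50 µm² | rejects sub-cellular specks |

## Interpretation choices in the event detector

The track-reconstruction parameters name two operations whose exact
definitions are not standardized; each is isolated in one function so
alternates can be swapped:

- **h value** is implemented as an h-maxima suppression: a connected
  suprathreshold component is kept only if it contains a regional maximum of
  prominence ≥ h (skimage reconstruction-based `h_maxima`, evaluated on a
  padded local patch).
- **Sharpness** is implemented as a spectral high-frequency-energy fraction:
  the unmasked local patch around a component is embedded in a fixed 128-px
  window, and the fraction of non-DC power beyond the k-space radius is
  compared to a cutoff (default 0.05). Focused tracks (σ ≈ 1 binned px) score
  ≈ 0.4; diffuse deep-crystal glows (σ ≈ 3.5 px) score < 0.01. The patch is
  deliberately unmasked so a broad glow whose top pixels barely clear the
  binary threshold still looks smooth.

Classification order: extent > max length → `long`; sharpness below cutoff →
`diffuse`; sharp single-pixel impulse → `sensor_hit`; otherwise `short`.
Only `short` events are accumulated (one increment at the nearest binned
pixel, round-half-away-from-zero); the grid total therefore equals the
accepted-event count exactly. Counts/min uses live time (dead time
contributes no observation window), and decay is corrected only back to the
tracer calibration time — decay *within* the acquisition is part of the
measurement, as in the emulated protocol.

## The synthetic-data generator

The simulator emulates the acquisition geometry and the published population
structure of a HeLa-FUCCI / [18F]FDG experiment; its defaults are the study
conditions, not free dials.

**Population.** Cycle-phase composition 27 % G1, 23 % G1/S, 50 % S/G2/M
(largest-remainder stratified allocation, so a 26-cell run is always
7/6/13 — the composition is part of the emulated design, not per-run
sampling noise; M/G1 is supported but defaults to zero, as none were observed
in the reference population). Per-phase dry-mass and counts/min medians and
lognormal spreads are derived from the published group medians and
interquartile ranges (e.g. G1 mass 422 pg with log-sd 0.095; S/G2/M counts
87/min with log-sd 0.28). Within a phase, counts couple to mass as
cpm ∝ m^β with β = 0.85, and the residual log-sd is set so the total
within-phase spread matches the printed IQR; β was calibrated once so the
ordinary-least-squares adjusted R² of counts vs mass averages the published
0.46 over many population draws (measured 0.464 over 400 draws). Cell radius
scales as m^(1/3) (12 µm at 604 pg).

**Phase/interferogram.** Cells are raised-cosine phase caps (smooth
boundaries like real phase images, C¹ at the rim); each cap's amplitude is
set by numerically inverting the dry-mass integral on the painted pixels, so
ground-truth mass is exact on the grid. The interferogram is
I = A + B·cos(2πf·r + Φ) with carrier (0.25, 0.15) cyc/µm (well below
Nyquist, sideband separable). Typical peak phases are 5–10 rad — genuinely
wrapped, exercising the 2D unwrapper.

**Fluorescence.** Reporter footprints times a smooth radial vignette
(strictly positive excitation field) plus offset and Gaussian noise; the
background frame carries the same vignette, which the normalization must
undo.

**RLM stack.** Per frame, each cell emits k ~ Poisson(activity · exposure ·
2^(−t/T½)) events split short/long/diffuse (0.70/0.15/0.15); short-track
centroids scatter around the cell centre with the PSF σ, long streaks
(length 12–20 binned px, i.e. always above the 10-px filter) start near
cells, diffuse blobs land uniformly; rare single-pixel sensor hits are added.
Frames are rendered directly at binned resolution with a 100-count baseline
and σ = 30 read noise; the dark stack is baseline + noise only. Dead time is
modelled as inter-frame gaps: it stretches the wall clock (and hence decay)
but not exposure. Each phantom's activity is set from its target
counts/min divided by the short-track fraction and the analytic capture
fraction 1 − exp(−R²/2σ²) of the PSF inside the dilated boundary, so the
*measured*, decay-corrected counts/min reproduce the published per-phase
medians.

**Track-shape defaults are assumptions.** The emulated study publishes no
quantitative track-shape model; the class shapes here (σ, peak ranges,
lengths) are simulator knobs chosen so the default filters separate the
classes cleanly — e.g. streak ridges stay above the binary threshold between
pixel rows (σ = 1 px, peak ≥ 1300), and diffuse peaks clear the threshold so
they are detected and then rejected by sharpness rather than silently
invisible.

**What the simulator does not model**, and hence what passing tests do not
show about real data: optical diffraction and coherent imaging artifacts,
EMCCD gain-register statistics (only additive/multiplicative noise),
scattering and depth-dependent blur inside the crystal, non-circular or
motile cells, fluorescence bleed-through, and track shapes of real positron
physics.

## Numerical choices

- **Sideband window**: circular, radius = half the carrier magnitude —
  the standard trade-off between resolution and zero-order leakage.
- **Unwrapping**: reliability-sorting 2D unwrap (skimage); adequate because
  cells are compact and smooth.
- **Background surface**: 2nd-order polynomial fitted on apparent cell-free
  pixels (|Φ| < 0.3 rad after median removal) and subtracted; otherwise
  residual tilt biases the mass integral. The recovered phase is defined up
  to a global sign (conjugate-sideband ambiguity); it is resolved toward
  positive bulk phase, since cells raise the optical path.
- **Steep-edge accuracy**: with realistic 8-rad peaks the windowed
  demodulation smooths the cell rim; per-pixel errors up to ~0.5 rad occur at
  the steepest edges while the mass *integral* stays within ~1 %. The
  sub-0.02-rad round-trip accuracy quoted in tests applies to gentle
  (≤ ~2.5 rad) profiles whose spectrum fits well inside the sideband window.
- **Segmentation threshold 0.15 rad**: low enough that the raised-cosine
  tail below the cut carries < 1 % of the mass at typical amplitudes; high
  enough to sit far above the demodulated noise floor at default noise.
- **Merge rule**: dilation by exact Euclidean distance transform; two cells
  are merged iff their dilated masks intersect (equivalently, edge gap
  < 2σ = 25 µm for convex cells); flagging is symmetric and merged cells are
  discarded. Cells touching the FOV border are excluded (their counts are
  truncated).
- **Mask downsampling**: a binned pixel counts as inside if its centre falls
  in the dilated mask, sampled at full-resolution index 8I+3 (the half-pixel
  convention bias, 0.3 µm, is negligible against the 12.5 µm dilation).
- **IRLS**: weights min(1, c·s/|r|) with s = MAD/0.6745 about the residual
  median; convergence when the coefficient change < 1e-8·(1+|coef|); a
  perfect fit (s = 0) short-circuits with weights 1. Non-convergence is
  flagged, never silent. Both the weighted and the plain OLS adjusted R² are
  reported, since which one a given study quotes is often ambiguous.
- **Mann–Whitney**: exact enumeration for ≤ 10 pooled observations without
  ties, normal approximation with tie correction otherwise; two-tailed
  doubling capped at 1.
- **Fluorescence expression threshold**: per-pixel cut at empty-region mean +
  3σ during normalization, then a per-cell summed-intensity threshold of 10
  (normalized units) — orders of magnitude above residual noise sums,
  orders of magnitude below real expression sums. Manual phase overrides are
  an explicit input (label → phase) and are recorded in the output, mirroring
  the visually-verified correction step of the emulated protocol.

## Problem sizes

Simulated acquisitions in the test suite and the acceptance script use
2,000–3,000 frames (40–60 s live time) instead of the full 20,000, and the
structural-reproduction check runs 20 seeded 26-cell fields of view; these
sizes give per-cell counts of ~40–90, enough to estimate population medians
while keeping a full run to a few seconds. The full 20,000-frame acquisition
is one `AcquisitionConfig` field away.

## Known limitations

- One field of view per run; pooling multiple experiments is plain table
  concatenation.
- The dry-mass integral uses the segmented (undilated) mask; mass in the
  sub-threshold rim (< 1 % at default amplitudes, more for very dim cells) is
  not recovered.
- Huber IRLS bounds but does not eliminate the influence of high-leverage
  outliers (no redescending ψ or MM-estimation).
- The sharpness score depends on a fixed 128-px analysis window; very large
  frames with dense events could place two events in one patch and blur the
  score.
- Simulated event classes are cleanly separable by construction; real
  track-morphology distributions overlap more, so the ≥ 0.95
  precision/recall demonstrated here is an upper bound on what identical
  settings achieve on real data.
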