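# Methods

## The measurement model

`fluctmap` treats a grayscale B-mode cine loop as a stack of intensity
frames `I_0 … I_{T-1}` sampled at a known frame rate and pixel spacing.
The quantity of interest is *temporal speckle decorrelation*: fully
developed speckle produced by fixed scatterers is deterministic, so a
stationary tissue region reproduces its speckle pattern exactly from
frame to frame, while internal motion of sub-resolution scatterers
(slow blood flow, wall deformation by arterial pulsation, acoustic
streaming — the mechanisms proposed for the hemangioma "fluttering"
appearance) rearranges the interference pattern and lowers the
frame-to-frame correlation.

The statistic is the windowed Pearson coefficient R between
consecutive frames, computed at every analysis point over a square
window of about 2 mm (the window size over which speckle statistics
are locally stationary but which still contains enough independent
speckle grains — at 0.2 mm/px the default window is 11 × 11 px). R is
invariant to any positive linear intensity map applied per frame, so
gain, per-clip min–max normalization, and (approximately) display
log-compression do not affect it.

Per-pair R values are aggregated into a **degree of coincidence**

    C(p) = mean over frame pairs t and neighbours q within ~2 mm of p
           of clamp(R_t(q), 0, 1)

and a **degree of fluctuation** F = 1 − C, quantized to
`level = round(255·F)`. Design choices embedded here:

* **clamp at 0** — anticorrelated speckle (R < 0) is no more
  "coincident" than uncorrelated speckle; the usable evidence scale is
  R ∈ [0, 1], which also matches the 255-gradation colour axis.
* **mean, not median/fraction** — the mean is linear, bounded, and has
  a closed-form expectation under the synthetic model (see below),
  which makes every stage oracle-checkable.
* **consecutive pairs** — the correlation is evaluated between frames
  n−1 and n for n = 1…T−1; a single forward pass, no temporal
  smoothing of R.
* **no padding** — windows and neighbourhoods must be fully supported;
  pixels near the frame edge are invalid rather than extrapolated, so
  no fluctuation evidence is fabricated at lesion borders. Validity
  masks are intersected across all stages.

## Motion cancellation

Bulk translation of the ROI (breathing, transmitted cardiac motion)
decorrelates speckle at a rate set by the point-spread function and is
the dominant false-positive mechanism. The model is one rigid 2D
translation per frame, estimated by exhaustive integer block-matching
NCC of the ROI pixels against **frame 0** (fixed reference, so errors
cannot accumulate over a 3.5 s clip), searched over ±8 px by default,
with deterministic tie-breaking (smallest |d|, then row, then col) and
optional 1D parabolic subpixel refinement per axis. Compensation
resamples frame t at p + d_t (exact integer indexing when d is
integer, bilinear otherwise) and marks out-of-frame samples invalid.
Rotation and deformation are deliberately not modelled: the target is
cancelling *overall* ROI movement, and a richer motion model would
absorb genuine internal fluctuation.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_frames` | 70 | frames | 3.5 s at 20 fps; enough pairs (69) to average speckle noise in C |
| `window_mm` | 2.0 | mm | local-stationarity scale of liver speckle; per-axis radius = round(mm/(2·spacing)), min 1 |
| `neighborhood_mm` | 2.0 | mm | same physical scale for spatial coincidence pooling |
| `search_radius_px` | 8 | px | residual breath-hold motion is a few px at 0.2 mm/px |
| `subpixel` | off | — | integer mode keeps estimates exact and tests bit-reproducible |
| `level_threshold` | 32 | level | see calibration below |
| `min_fraction` | 0.05 | — | a "coloured area" must cover a meaningful part of the lesion |
| `min_component_px` | 25 | px | ≈ 1 mm² at 0.2 mm/px; isolated bright pixels are speckle noise, not an area |
| `display_min_level` | 32 | level | overlay floor aligned with the call threshold, so what is called is what is shown |
| `alpha` | 0.5 | — | overlay opacity |

### Calibration of the positivity threshold

Under the AR(1) flutter model (below), a lesion whose complex field
keeps per-frame correlation ρ has one-lag envelope correlation ≈ ρ²,
so its expected fluctuation score is F ≈ 1 − ρ². The per-pair
statistic at 20 fps sees only 50 ms of decorrelation: even a vividly
fluttering lesion (whose speckle fully decorrelates over ~0.5 s,
ρ ≈ 0.9) only reaches F ≈ 0.19 (level ≈ 48) — the human impression of
strong flutter integrates change over many frames, while R does not.
A threshold at the palette's yellow anchor (170) would therefore
detect only near-total per-frame decorrelation and miss every moderate
flutter. The default `level_threshold = 32` (F = 0.125, i.e. a lesion
losing ≥ 12.5 % of its speckle correlation per frame interval,
ρ ≲ 0.93) was fixed from this closed-form analysis: it sits a factor
~1.5 below the ρ = 0.9 operating point and a factor ~8 above the
level of static tissue with a realistic noise floor (level ≲ 5 at
noise σ = 0.01). All three call parameters remain explicit CLI
options, and the palette still reaches yellow/red for strong
decorrelation.

## The synthetic-data generator

`fluctmap.synthetic` emulates the features of B-mode cine loops that
the method actually measures:

* **speckle** — envelope magnitude of complex circular white Gaussian
  noise convolved with a separable Gaussian PSF (σ = 1.5 px axial ×
  2.0 px lateral); point intensities are Rayleigh (SNR =
  √(π/(4−π)) ≈ 1.913), spatial correlation set by the PSF.
* **flutter** — inside a ground-truth mask the field evolves as
  z_t = ρ·z_{t−1} + √(1−ρ²)·w_t. ρ is the single knob and ties
  directly to the measured statistic (F ≈ 1 − ρ²), enabling
  parameter-recovery tests; the ρ presets are engineering choices, not
  physiological claims — the true decorrelation magnitude in
  hemangiomas is unknown.
* **pulsation** — global sinusoidal translation (default 2 px at
  1 Hz) along the axial axis, rounded to integer pixels and realised
  by cropping a moving window from a padded field: translation is
  exact, with no wraparound or interpolation artefacts, so the motion
  estimator can be tested for *exact* recovery.
* **noise** — additive Gaussian intensity noise after normalization
  (default σ = 0.01 in flutter fixtures, 0 in the static fixture so
  the null is exact).

Default clip geometry: 70 frames, 96 × 96 px at 0.2 mm/px, 20 fps,
flutter disc of radius 18 px (3.6 mm), analysis ROI 64 × 64 px — about
four times the lesion area, comfortably above the
twice-the-lesion-area guidance the pipeline warns about. These sizes
keep a full pipeline run below a second while leaving > 1000 lesion
pixels and 69 frame pairs for stable statistics; the acceptance script
runs ~30 such simulations in well under a minute.

What the generator does **not** model: log-compression nonlinearity
(available as an option, but R's linear invariance makes it nearly
irrelevant), depth-dependent PSF and attenuation, scan-conversion
geometry, out-of-plane motion, tissue deformation, and the actual
biophysics of hemangioma flutter. Passing tests therefore demonstrate
that the pipeline measures AR(1)-style temporal decorrelation
correctly and rejects rigid-translation artefacts — not that it
reproduces clinical sensitivity/specificity on patient data.

## Numerical choices

* Window statistics via separable moving sums (float64); agreement
  with the naive double-sum formula is ~1e−15 per pixel and asserted
  at 1e−10.
* R is clipped to [−1, 1] to absorb last-ulp excursions; identical
  windows give R = 1 within one ulp, so the static-clip null is
  asserted as level ≡ 0 and |F| ≤ 1e−12.
* Zero-variance windows (variance ≤ 1e−12 on [0,1]-scaled data) are
  invalid rather than 0/0.
* Half-up rounding everywhere a real value becomes an integer (levels,
  mm→px radii, overlay blending) — deterministic and
  platform-independent.
* Block-matching ties broken by (|d|², d_row, d_col) ordering with
  strict improvement, so the zero shift wins all-equal surfaces.
* All randomness flows from `numpy.random.default_rng(seed)`; the
  generator is bit-reproducible and every artifact (maps, PNGs,
  summaries) is byte-identical across reruns.

## Agreement statistics

Cohen's κ on the 2 × 2 reader-vs-software table, with the
Fleiss–Cohen–Everitt large-sample variance and a Wald 95 % CI
truncated to [−1, 1] (delegated to `statsmodels`, cross-checked in the
tests against an independent closed-form evaluation). Degenerate
tables (pe = 1) raise instead of returning NaN. Note for users
comparing against the published hemangioma reader study: the printed
2 × 2 cells (34, 4, 0, 28) give κ = 0.878 [0.763–0.993] by the
standard formula — not the κ = 0.95 [0.74–0.99] printed alongside
them, and the cells sum to 66 while the cohort is 62 — so this package
pins the value its own formula produces and no test targets 0.95.

## Known limitations

* Translation-only motion model; rotation/deformation leak into F.
* The coincidence statistic and neighbourhood size of the original
  scanner-integrated implementation are unpublished; this package's
  definitions (documented above) are one principled realisation, and
  absolute F values are not comparable across different choices.
* The call thresholds are calibrated on the synthetic model, not on
  clinical data; on real clips they are starting points, not validated
  operating points.
* No real-time operation: the analysis is retrospective on saved
  clips.
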