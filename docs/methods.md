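# Methods

This note documents the models, algorithms and numerical choices behind
`cellquant`, and what its synthetic validation does and does not
demonstrate about real data.

## Camera response model

The camera response function (CRF) is modeled as a cubic polynomial
`g = f(E) = a₁E + a₂E² + a₃E³` on normalized axes: irradiance `E ∈ [0,1]`
and gray level `g ∈ [0,1]` (gray 255 ↔ 1). Exposure-bracketed images of a
static scene determine the response only up to an overall scale, so the
gauge is fixed by `f(0) = 0` and `f(1) = 1` (equivalently `Σaᵢ = 1`); a
cubic is flexible enough for typical CCD non-linearity while remaining
analytically invertible.

**Self-calibration objective.** Because scene radiance is constant, a
pixel's irradiance scales exactly with exposure time, so for any image
pair `f⁻¹(g_j) = (t_j/t_i)·f⁻¹(g_i)`. The fit proceeds in three stages:

1. *Linear stage.* The inverse response `h(g)` is expanded in a polynomial
   basis (degree `2·d−1` for a forward degree `d`, so the inverse of a
   cubic is representable to well below one gray level) with `h(0)=0,
   h(1)=1`, and fitted by ridge-regularized least squares on the pair
   constraints `h(g_hi) − R·h(g_lo) = 0`. The Tikhonov weight is chosen at
   the corner (maximum curvature in log–log coordinates) of the L-curve
   over 50 log-spaced weights, restricted to weights whose solution is a
   monotone — physically admissible — response.
2. *Forward refit.* A cubic `f` with the same gauge is fitted through the
   recovered `(E, g)` curve.
3. *Polish.* The forward coefficients (only `d−1` free parameters) are
   refined directly against the pair constraints by bounded trust-region
   least squares, multistarted from the linear-stage estimate and the best
   points of a coarse grid over monotone cubics. A soft penalty keeps the
   response monotone during optimization: non-monotone cubics can fake
   small pair residuals through spurious root branches, and unbounded
   steep responses make all residuals vanish, so both failure modes are
   excluded by construction rather than by luck.

**Pair collection.** Every image pair at distinct exposures contributes
per-pixel `(g_lo, g_hi, t_hi/t_lo)` triples, capped at 10⁵ seeded samples
per pair. Saturated pixels (255) are excluded because they carry no
radiometric information. Pixels at or below a dark floor (default 20 of
255) are excluded as well: the constraint is an errors-in-variables
problem, and near the floor the quantization and read noise of the short
exposure is amplified by the exposure ratio, which measurably biases the
fit long before it degrades the well-exposed range.

**Inversion.** The fitted cubic is inverted with Cardano's closed-form
solution (trigonometric branch for three real roots), selecting the unique
root in `[0,1]` and breaking numerical ties by continuity with the
neighboring entry. One Newton step polishes each root — the closed forms
lose a few digits to cancellation on near-degenerate cubics — bringing the
round-trip residual `|f(LUT[g]) − g/255|` to machine precision. The
256-entry look-up table is saved as a plain-text file with the cubic's
coefficients in its header.

**Vignetting** is corrected additively: the correction field is
`median(flat) − flat` for a flat-field image of a uniform emitter, so the
corrected flat is constant. The QC report flags exposures whose smoothed
flat has a relative range of 2% or more (boundary inclusive). Additive
correction restores spatial uniformity up to a global offset, which the
calibrator normalization absorbs.

## Pre-processing

Stages run in the order: gray conversion (replicated-RGB containers
collapse to one channel; differing channels fall back to the first with a
warning), optional vignetting addition, background subtraction, CRF
linearization. A `linearize_first` switch performs subtraction in linear
space instead; it is off by default to match the reference protocol order.

**Background subtraction** estimates the background as the grayscale
opening of the image with a disk (default radius 15 px — at least the
half-width of a cell, so cells are removed while background structure of
any shape survives) and subtracts it pixel-wise. Because the opening is a
min-then-max filter, on a noisy image it sits below the true background by
roughly the noise amplitude, which would bias every cell's fluorescence
upward (+15% at SNR 10 in simulation). The difference image is therefore
recentered by its median — exactly zero for noise-free inputs whenever
cells cover less than half the field, so the correction changes nothing in
the noise-free limit — and then clipped at zero.

**Linearization** replaces each gray level with its normalized irradiance
via the LUT and divides by the exposure time, making samples acquired at
different shutter speeds directly comparable. Saturated pixels are
retained but counted; a saturated fraction above 1% logs a warning to
shorten the shutter.

## Segmentation

Edges are zero crossings of the Laplacian-of-Gaussian response (default
σ = 2 px): a pixel is marked when its left/right or up/down neighbors
straddle a sign change **and** its Gaussian gradient magnitude exceeds a
threshold. The threshold defaults to 3× the median of the gradient
magnitude — a robust scale set by the background noise, since cells cover
a small fraction of the field — so spurious-edge suppression adapts to the
image's noise level; on pure noise it leaves a few edge pixels per
thousand, and 4× leaves under 0.1%.

Closed contours are filled by border-seeded hole filling (broken contours
stay open and produce nothing), followed by a finishing erosion with a
3×3 cross. The erosion equalizes pre- and post-segmentation cell size and
is set-up-specific: the straddle-pair discretization marks a band about
two pixels wide just outside a sharp cell boundary, so the pipeline
default is 2 iterations (calibrated once against the simulator's
geometry), while the function default stays at 1 and the stage can be
disabled for optics that do not need it.

Connected components (8-connected) outside the inclusive area band
[20, 2000] px are removed and counted; survivors are renumbered in
raster-scan order. Per-cell fluorescence is the arithmetic mean of the
irradiance image over exactly the cell's pixels; per-image density is the
cell count divided by the slide-preparation volume (3 μL by default), with
an optional field-of-view scaling factor (default 1, i.e. the literal
count-over-volume definition). Touching cells are **not** split — they
merge into one component and are typically removed by the area filter;
scenes are expected sparse, and this is a documented limitation.

## Population statistics

Values are normalized by the mean of a calibrator sample measured in every
session (the maximally induced culture), so multiplicative drifts — lamp
aging, temperature, day-to-day gain — cancel; the calibrator itself
normalizes to mean exactly 1. Populations are equalized to a common
cardinality (default 12×10³ cells) by seeded subsampling without
replacement before comparison. Statistics use the sample (n−1) standard
deviation; noise is CV² = (σ/μ)², which is invariant under the calibrator
normalization and under exposure rescaling. The standard error is computed
across biological-replicate means when replicate structure is provided,
else as σ/√n, and the method used is recorded. The Mann–Whitney U test
uses exact enumeration for tie-free groups of ≤20 and the normal
approximation with tie/continuity corrections otherwise (the documented
floor is 2 values per group, with a warning under 8). Cross-instrument
fits are ordinary least squares of degree 1 or 2 on condition-level
(replicate-averaged) values, reported with R² and MSE.

**Photobleaching QC** compares the mean fluorescence of the first and last
⌊n/3⌋ images of a slide, in acquisition order; the slide passes when
last/first ≥ 0.95. The default acquisition caps — 15 images and 120 s per
slide — keep the decay of a well-behaved fluorophore inside that band.

## Synthetic scenes

The simulator emulates what the pipeline must be robust to, with exact
ground truth:

- **Geometry**: spherocylinders (rectangles with semicircular caps),
  lengths 18–32 px and widths 6–9 px at the default 512×512 field —
  rod-shaped bacteria at ~40x with cells a few hundred pixels in area.
  Placement is by rejection sampling with a 5 px minimum separation, so
  segmentation tests measure detector quality rather than the (absent)
  touching-cell splitting; an `allow_touching` flag exists for stress
  tests. Over-dense requests fail with the achievable density named.
- **Fluorescence**: per-cell values are log-normal — strictly positive,
  with mean m and CV² c set exactly via σ²_log = ln(1+c),
  μ_log = ln m − σ²_log/2. Defaults m = 0.5, c = 0.09.
- **Acquisition**: irradiance = background (default 0.1, optionally with a
  planar gradient) + cell fluorescence × exp(−bleach rate × cumulative
  excitation time), optionally blurred by a Gaussian PSF (default off:
  ideal binary edges; σ = 1 px emulates optics), dimmed radially by a
  vignetting amplitude, scaled by exposure/reference-exposure, clipped to
  the CRF domain (the clipped fraction is reported as saturation), mapped
  through the cubic CRF, and quantized to 8 bits after additive Gaussian
  read noise (default sd 5 gray; Poisson shot noise behind a flag).
  Everything is deterministic given the seed.

What the simulator does **not** model — diffraction-limited PSF structure,
3-D cells, division and growth, intracellular heterogeneity, spatially
varying CRF — bounds what a passing validation shows: the pipeline
recovers what this forward model generates. Real micrographs add optical
blur (the per-cell means then include genuinely dimmer boundary pixels),
focus drift and debris, so absolute biases on real data can exceed the
synthetic figures even when the comparative statistics (normalized dose
responses, CV² profiles) remain reliable.

## Validation benchmarks and problem sizes

The validation suite (`cellquant.validation`, exercised by the test suite
and `scripts/acceptance.py`) uses these reference conditions:

- CRF: 1000 random monotone cubics for inversion exactness; recovery from
  4 exposures of 1–4 ms of a 128×128 static ramp phantom through the
  identity and a known cubic response.
- Segmentation: 20 scenes × 100 non-touching rods at SNR 5 (amplitude over
  read-noise sd); precision/recall matched by detected-centroid-inside-
  true-footprint.
- Quantification: median per-cell bias at SNR 10 over 5 scenes; exposure
  invariance on a uniform-fluorescence scene at exposure scales 0.4/0.8
  with light dithering noise (8-bit quantization cannot average out over
  internally uniform cells, so the noise-free check would measure the
  quantizer, not the linearization).
- Noise statistics: CV² ∈ {0.01, 0.04, 0.09, 0.25, 0.49} at n = 12×10³
  cells, judged against bootstrap standard errors (200 resamples).
- Cross-instrument analog: 5 induction levels (means 0.08–0.95, CV² 0.09),
  4 scenes of 100 cells per level (~400 measured cells per level — enough
  that the condition-level fit and adjacent-level rank-sum tests are far
  from their thresholds, at a fraction of the rendering cost of a
  cytometer-scale 12×10³ cells per level); per-level shutter adaptation
  places the mean at ~55% of the gray range, and the linearization
  restores comparability.
- Subgroup stability: disjoint subgroups of 10–3000 cells from n = 12×10³
  populations whose CV² varies across conditions (0.49 down to 0.01, as in
  an induction series), correlated per size against the full-population
  profile.
- Density: true counts {25, 50, 100, 200, 400} in an 800×800 field (the
  largest count cannot be placed without touching in the default field).
- Photobleach QC: 21 decay rates spanning pass and fail, checked against
  the closed-form first/last-third ratio of the exponential.

## Known limitations

- No touching-cell splitting (watershed or contour-based); dense cultures
  under-count.
- The cubic CRF is global: no per-channel or spatially varying response.
- Background subtraction on gray levels before linearization follows the
  reference protocol but is an approximation when the CRF is strongly
  non-linear; `linearize_first` exists for the physically exact order.
- Self-calibration accuracy degrades with read noise (errors-in-variables
  bias); the dark-floor exclusion mitigates but does not eliminate this.
- Density uses the literal count-over-volume definition; absolute
  densities require the field-of-view fraction to be calibrated for the
  instrument.
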