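# Methods

## Model and pipeline

A brightfield micrograph of absorbing histological dyes is modeled with the
Beer–Lambert law. After flat-field correction the pixel value is transmittance
`I ∈ [0, 1]` per color plane, and optical density `OD = −log₁₀ I` is additive
across co-localized dyes:

    od(x) = c₁(x)·v₁ + c₂(x)·v₂ + c₃(x)·v₃

with `v₁, v₂` the unit-norm OD color vectors of the differentiation dye and
its counterpart, `c_s ≥ 0` the per-pixel stain amounts, and `v₃` a residual
direction. The pipeline is, in order: flat-field correction → OD transform →
linear unmixing → 8-bit transmittance re-encoding per channel → global
auto-threshold per channel → area fractions → differentiation ratio (DR) →
donor aggregation, normalization (DRᴺ) and the repeated-measures ANOVA.

Assumptions worth stating: dyes absorb rather than scatter (dyes with strong
scattering or neutral gray color cannot be unmixed this way); stain amounts
are proportional to chromogen, not to analyte, so DR compares area coverage,
not protein concentration; calibration frames share the acquisition settings
of the images they correct.

## Flat-field correction

`corrected = (O − D) / (L − D)` per pixel and per color plane, clipped to
[0, 1]. Dark subtraction cancels additive fixed-pattern noise (hot pixels
with elevated dark current appear identically in O, D and L); the quotient
removes multiplicative shading (vignetting, uneven well transmittance).
Correction is per color plane, not luminance-based, because the stain vectors
are defined per plane. Values above 1 (specimen brighter than the empty well)
are clipped and the pre-clip fraction is logged per image.

Calibration sites where `light ≤ dark` (saturated/dead pixels, which
subtraction cannot fix) are repaired by the median of their valid
8-neighbors, iterated at most 10 times; if more than 1% of sites are invalid
the pair is rejected outright — a pair that defective needs recapture, not
repair.

## Unmixing and channel encoding

- OD uses base-10 logarithm with floor `ε = 1/255` (one half-step below the
  smallest nonzero 8-bit level); floored pixels are counted per image.
- The residual vector is the normalized cross product `v₁ × v₂`, sign-flipped
  when its component sum is negative; the unmixing matrix is the exact inverse
  of the row-stacked basis.
- Negative concentrations (OD outside the stain cone, from noise or unmodeled
  dyes) are floored to zero after counting.
- Channels are re-encoded as `clip(round(255·10^(−c)), 0, 255)` with
  round-half-away-from-zero, so stained pixels are dark and tests are
  bit-exact.
- Stain presets (hematoxylin, Oil Red O, Alcian Blue, Nuclear Fast Red,
  Alizarin Red S, and the purple non-mineralized osteogenic background) are
  starting points only; color vectors depend on instrument and protocol and
  should be calibrated per study with `estimate_stain_vector` (mean OD over a
  single-dye ROI of ≥ 10 visibly stained pixels, unit-normalized).

## Thresholding

Otsu's method is implemented directly on the 256-bin histogram: the threshold
maximizing the between-class variance of the cut `class 0 = {value ≤ T}`,
ties broken toward the smallest T. Positivity is `value ≤ T` globally
(transmittance coding), which removes a silent sign error. Thresholds are
computed per channel per image — acquisition settings are fixed, the
automatic rule adapts — with `mean`, `isodata` and `triangle` available
(delegated to scikit-image) and a study-wide fixed threshold as a config
switch. A constant channel makes variance-based methods degenerate and raises
an error naming the image; for pellet masking such channels are treated as
unstained instead.

## Aggregation and statistics

Nested means (images → well → donor) rather than pooled grand means:
identical for balanced designs, well-defined under dropouts; undefined DRs
(counterpart area 0) are excluded with a logged count. DRᴺ divides the
donor's differentiated mean by its control mean; a donor with no usable
controls uses the arithmetic mean of the other donors' control means
(`control_source = pooled-fallback` in the summary).

The ANOVA operates on donor × condition means — one value per cell, the only
structure the two-condition repeated-measures design supports without
positing replicate covariance. `F = MS_condition / MS_(donor×condition)` on
(1, n−1) df; with two conditions this is exactly the squared paired t. The
interaction SS is computed from explicit residuals
`y_ij − ȳ_i· − ȳ_·j + ȳ`, not by subtracting totals, which keeps the F = t²
identity at machine precision; sums of squares below rounding noise
(10⁻¹⁴ × the data's sum of squares) are treated as exact zeros, so a table
with identical conditions returns F = 0, p = 1 rather than a ratio of
rounding errors. Zero interaction with a nonzero effect is reported as
F = +∞, p = 0 with a warning — reproducible behavior on pathological input,
not an exception. Pellet areas are compared between conditions with the same
test on per-donor mean areas.

## Synthetic data: what it emulates, and what it does not

The generator renders the forward model:
`I = round(dark + hot + A·vignette·10^(−Σ c_s v_s) + noise)` per plane,
clipped to [0, 255], with `A = illumination_scale · 255`. Defaults for whole
studies (chosen once as a realistic desk-scale acquisition):

| parameter | default | meaning |
|---|---|---|
| replicate structure | 3 wells × 4 images (3 sections for pellet assays) | per donor and condition |
| image size | 128 px square (64 px in fast test fixtures) | field of view |
| control stained fraction | 5% | channel-1 area in non-induced wells |
| counterstain fraction | 15% | channel-2 (nuclear) area, condition-independent |
| stain amounts | c₁ = 1.0, c₂ = 0.7 OD | region concentrations |
| vignette corner gain | 0.85 | multiplicative shading |
| illumination scale / dark level | 0.8 / 6 | keeps hot sites below saturation |
| hot pixels | 5 sites, +40 offset | additive fixed-pattern noise |
| intensity noise σ | 2 gray levels | additive Gaussian, post-transform |
| per-image jitter | lognormal, CV 8% | biological well-to-well scatter |

Differentiated wells carry a stained fraction equal to a per-donor effect
multiplier times the control fraction. Blob regions cover an exact pixel
count (top quantile of a smoothed noise field), so ground-truth area
fractions are exact; truth tables record every per-image fraction and each
donor's expected DRᴺ. A fixed seed determines every byte of the tree.

What passing on this generator does **not** show: real stains have spatially
varying chromogen density, out-of-focus blur, overlapping dyes, scattering
components and stain-vector drift between batches; none of these are
modeled (no photorealistic histology, no PSF). Results on real material
therefore still depend on per-study stain-vector calibration and on visual
inspection of thresholds.

The ANOVA calibration (type-I error of the F test at α = 0.05 on null
studies) is run on statistically simulated studies — lognormal image-level
DRs fed through the same nested-mean aggregation and the same F test — with
500 replicates of 6 donors. Simulating at the DR level isolates the layer
the calibration concerns and makes hundreds of replicates cheap; the pixel
pipeline's own behavior is covered by the rendered end-to-end studies. Note
the exact null mean of F(1, 5) is 5/3, not 1, so calibration is asserted via
the rejection rate, not the mean F.

## Numerical choices and degenerate inputs

- 16-bit input is rejected unless an explicit downscale is requested; bit
  depth is never converted silently. RGBA is accepted only with constant
  alpha.
- Study discovery is a pure function of the path set (lexicographic order at
  every level); reruns produce bit-identical CSVs.
- A donor present in one condition only is retained with a warning; an
  all-white image raises a degenerate-histogram error naming the image; a
  study aborts only when more than half of its images fail.
- DR with a zero denominator is NaN (undefined), retained in records,
  excluded from means.
- `auto_pellet_area` takes the largest connected component of the union of
  both stain masks, so detached debris does not inflate the area;
  manual-ellipse mode (`πab/4` from measured axes) is the reference mode.

## Known limitations

- Two stains only; the residual channel is computed for QC but never
  thresholded.
- No adaptive/local thresholding and no morphological cleanup.
- No retrospective shading correction: a Dark/Light pair is required.
- The univariate donor-level ANOVA does not model within-donor replicate
  covariance; with two conditions no sphericity correction is needed.
- Pixel sizes come from configuration, not image metadata; microscope
  magnification alone does not determine µm/px.
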