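# Methods

## Overview

`vineyield` estimates per-vine grape yield from RGB images of the
fruiting zone in two steps: an unsupervised segmentation that counts and
sizes clusters, and a linear calibration from summed 2-D cluster surface
to harvested mass. Every stage is deterministic given its inputs; all
stochastic components (the synthetic scene and vine-table generators)
are driven by a single PCG64 seed.

## Color pipeline

Images are 8-bit sRGB. The conversion chain is the CIE standard:
sRGB transfer de-gamma (IEC 61966-2-1) → linear RGB → XYZ with the
BT.709/D65 matrix → CIELAB. The reference white is taken as the XYZ
image of unit linear RGB under the same matrix rather than from
tabulated illuminant values; the practical consequence is that any gray
input lands exactly on the neutral axis (a\* = b\* = 0), which the test
suite asserts to 1e-6. Against an independent colorimetric
implementation (scikit-image's `rgb2lab`) the channels agree to better
than 0.01 everywhere; the residual is the white-point tabulation
difference.

Only the b\* plane is used downstream: ripe dark berries have
low/negative b\*, while green-yellow foliage and brown soil are clearly
positive. All channel arithmetic stays in float64; nothing is quantized
to 8 bits until histogramming.

Smoothing is a Gaussian with σ equal to the configured "radius"
(default 2 px) and symmetric (half-sample reflect) borders, which makes
the filter exactly mass-conserving — the channel mean is preserved to
1e-9. The radius→σ identification is a configuration choice
(`gaussian_radius`); any other interpretation of "radius" can be tested
by passing a different value.

## Two-stage thresholding

Histograms use 256 linear bins spanning the min–max of the included
pixels (8-bit-equivalent behavior independent of the channel's physical
scale). Otsu's threshold maximizes the between-class variance
σ²_B(t) = ω₀(t)ω₁(t)[μ₁(t) − μ₀(t)]², evaluated exhaustively over all
255 splits with vectorized cumulative sums; ties break to the lowest
bin. The returned threshold value is the upper edge of the threshold
bin, so adding a constant to the channel shifts the threshold by that
constant to within one bin width.

Stage 1 thresholds the full histogram and removes the above-threshold
(high-b\*) class as vegetation. Stage 2 rebuilds the histogram on the
remaining pixels only — re-ranged to their min–max, which re-stretches
the contrast between soil and fruit — and labels the below-threshold
(low-b\*) class as cluster. The polarity is configurable
(`cluster_polarity="high"`) for targets brighter than their background
(e.g. white cultivars against dark nets), and the re-ranging choice is
isolated in `build_histogram` should a fixed-range variant be needed.

Otsu's criterion always produces *some* split, including on an
effectively one-class histogram (an image with no fruit, or no
vegetation). Stage 2 therefore applies a bimodality guard: the Ashman
separation of the two induced classes,
D = √2·|μ₁ − μ₀| / √(σ₀² + σ₁²), must reach 4.0. Splitting a unimodal
Gaussian at its Otsu threshold yields D ≈ 2.65 independent of scale,
while genuine fruit/background splits in both synthetic regimes measure
D ≈ 8–19, so the default threshold sits between the two with a wide
margin. Stage 1 carries no such guard because its below-threshold class
legitimately contains two modes (fruit *and* soil), which deflates D;
a unimodal image that slips through stage 1 is still caught at stage 2.
Degenerate stages fail soft: the mask returns with zero cluster pixels
and a per-stage status flag so batch runs continue.

## Particle analysis

Cluster pixels are labeled 8-connected (configurable to 4). Per
component the package records pixel area, chain-code boundary perimeter
(straight steps 1, diagonal √2, as implemented by
`skimage.measure.regionprops`; a 10×10 square has perimeter 36),
circularity 4πA/P² capped at 1.0, centroid and bounding box. With a
scale calibration (pixels per cm, optionally derived from a
known-length line target) areas are also reported in cm²; yield
operations refuse uncalibrated sets rather than silently mixing units.

Retention filters default to area ≥ 200 px (inclusive) applied to raw
pixel areas, and circularity within the closed range [0.25, 1.00] —
the standard analyze-particles settings for bunches imaged at roughly
2 mm ground resolution. Both are monotone: tightening either filter can
only reduce the retained count.

Two bunches hanging close together are often segmented as one oversized
blob. The double-cluster adjustment counts any particle whose area
exceeds `split_factor` × median area of its image as exactly two
(never three or more); the default factor 1.5 is chosen against the
within-vine bunch-size spread of the synthetic scenes (≈15% area CV),
where the largest of eight bunches stays below ≈1.3× the median, so a
genuine single bunch essentially never trips the rule while a merged
pair (≈2× median) always does. The factor is configuration-exposed; on
real imagery with broader size spread it should be re-examined.

## Yield model

Per vine, the retained calibrated areas are summed and regressed
against ground-measured yield: ordinary least squares with intercept
(`through_origin=True` forces β₀ = 0 for the view that zero visible
surface implies zero yield). The fit is delegated to statsmodels OLS;
results carry slope (g/cm²), intercept (g), standard errors, R² and
training size, serialize to JSON, and apply to later seasons
(`results.apply(records)`), clamping negative predictions to zero with
a warning. Vines from both vigor zones are pooled in one fit; per-zone
fits are a caller-side subset operation.

## Evaluation metrics

* TPR = detected(adjusted)/observed × 100 — a count ratio, not clamped,
  so systematic over-counting is visible as TPR > 100.
* TPR_Ripe divides by (observed − green): unripe green bunches are
  colorimetrically indistinguishable from foliage on b\* and are outside
  the method's reach by design.
* percent error = (measured − estimated)/measured × 100 (signed,
  positive = under-estimate); accuracy = 100 − |percent error|, which
  treats over- and under-estimation symmetrically and can go negative
  for errors beyond 100%.
* NDVI = (R_nir − R_red)/(R_nir + R_red) for vigor zoning of
  multispectral mosaics.

Metrics broadcast over arrays, supporting both single-vine and
mean-of-vines computation.

## Cost model

Survey and elaboration times per hectare (ground: 25 and 2 min/ha; UAV:
1 min fixed + 2 min/ha and 10 min/ha) are converted to hours and
rounded half-up to 0.1 h *before* multiplication by the man-hour rates
(ground $16/$16, UAV $24/$20); the UAV mode adds $620 of equipment
depreciated over 3 years ($206.7/yr, one survey per year). Rounding
times before costing is deliberate: at the 0.1 h resolution the ground
elaboration legs (0.17–1.7 h) are where the two orders of operations
visibly differ, and this implementation consistently rounds first.
Decimal arithmetic is used for the half-up roundings so that values
like 0.35 h round up reliably.

## Synthetic scenes

The generator renders a 480×360 px fruiting-zone view: a foliage band
over the top 60%, soil below, and by default 8 clusters (the high end
of per-vine counts in the emulated system) placed in a band under the
canopy with a guaranteed inter-cluster gap of ≥8 px, so ground-truth
bunches are pairwise disconnected. Region colors (foliage (70,120,50),
soil (110,95,85), berries (60,40,80) sRGB) were picked for their b\*
geometry — foliage ≈ +33, soil ≈ +8, berries ≈ −21 — matching the
opponent-channel ordering that the method exploits on real imagery.
Each bunch is a union of 4 jittered ellipses rescaled to area 1.8 r²
with r ~ N(16, 1.2²) px, giving lumpy compound outlines with ≈15%
within-scene area spread. Per-pixel labels and per-cluster rendered and
visible areas are recorded before additive Gaussian sensor noise
(sd 3, clipped to [0, 255]).

Acquisition regimes:

* best condition — occlusion 0.05, shade 0.05: bunches sunlit and
  nearly free of leaves;
* worst condition — occlusion 0.5, shade 0.4: half of each bunch's
  pixels overdrawn by leaf ellipses (leaf size capped by the remaining
  cover budget, so light occlusion means small leaf bits and heavy
  occlusion fragments the visible fruit), plus dappled multiplicative
  shade from a Gaussian-smoothed random field (σ = 32 px). Shade is a
  smooth field, never a hard edge: hard shadow boundaries would create
  a second soil histogram mode and make stage 2 split soil against
  soil, which is a rendering artifact rather than the field failure
  mode (leaf cover blocking line of sight).

Under these defaults the pipeline finds essentially every bunch in best
condition (mean count TPR ≈ 100%, per-scene error within ±1 across 100
seeds) and misses most in worst condition (mean TPR ≈ 35–45%), because
occlusion fragments fall below the 200 px floor — the same direction
and rough magnitude of degradation reported for leaf-covered, shaded
fruit in the field.

What the generator does **not** emulate: perspective and out-of-plane
geometry, specular highlights and sensor vignetting, continuous color
gradients across ripening, background trellis hardware, neighboring-row
bleed-through, and motion blur. Passing tests therefore demonstrate the
algorithmic correctness and the qualitative condition ordering, not
field-level detection rates.

The vine-table companion draws per-vine cluster surfaces from the
vigor-zone distributions (high vigor 168.6 ± 84.0 cm², low vigor
69.2 ± 35.6 cm², truncated at 10 cm²) and yields from a true line
(default slope 4 g/cm², intercept 0) plus Gaussian noise with sd equal
to 15% of the zone-mean yield. These support parameter-recovery tests:
the mean fitted slope over 500 seeded 10-vine tables lands within 5% of
truth, and zone-mean accuracy on held-out tables — itself a noisy
statistic at 10 vines/zone (sd ≈ 5 points) — is estimated as the mean
over seeded replicate season pairs, ≈ 92–95%.

## Problem sizes

Default verification runs use 480×360 px scenes (20 per acquisition
condition), 200 random histograms for the Otsu oracle, 500 seeded
10-vine tables for slope recovery and 20 season pairs for held-out
accuracy; the full suite and the acceptance script each complete in
well under a minute of CPU apiece at these sizes, and all of them scale
linearly if larger studies are wanted.

## Known limitations

* The Lab transform constants of other software (different white-point
  tabulations, ICC-managed pipelines) differ in the third decimal;
  comparisons across implementations should use tolerances, not
  equality.
* The double-cluster rule is a count heuristic: it never splits the
  *area* of a merged blob, so summed surface (and hence yield) is
  unaffected by the adjustment.
* Otsu-based segmentation assumes a fruit population large enough to
  form a histogram mode; scenes where fruit occupies well under ~1% of
  the non-vegetation pixels may be rejected by the bimodality guard.
* The cost model reproduces a fixed published scenario; rates, times
  and depreciation are parameters, not market data.
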