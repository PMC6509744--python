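# vineyield

Unsupervised grape-cluster detection and pre-harvest yield estimation
from high-resolution RGB images of vine fruiting zones (e.g. low-cost
UAV imagery of a vertically shoot-positioned canopy).

Manual pre-harvest yield sampling — walking rows, counting and weighing
bunches on a handful of vines — is slow and often unrepresentative.
This package implements a fully unsupervised image pipeline that counts
and sizes grape clusters weeks before harvest and converts their 2-D
surface into grams per vine:

1. **Color transform** — sRGB → CIELAB (D65); dark blue-purple berries
   sit at low/negative b\* (the blue–yellow opponent), foliage and soil
   at positive b\*.
2. **Smoothing** — Gaussian filter (σ = 2 px) on the b\* plane to clean
   the histogram.
3. **Two-stage Otsu thresholding** — the first threshold removes the
   high-b\* vegetation class; the histogram is rebuilt on the remaining
   pixels and a second threshold isolates the low-b\* cluster class.
   Each stage maximizes the between-class variance
   σ²_B(t) = ω₀ω₁(μ₁ − μ₀)²; a split is rejected as degenerate when the
   Ashman separation D = √2·|μ₁ − μ₀|/√(σ₀² + σ₁²) of the two classes
   falls below 4 (a unimodal histogram split in half gives D ≈ 2.6).
4. **Particle analysis** — 8-connected components, calibrated area
   (cm², from a known-length target), perimeter and circularity
   4πA/P²; retention filters area ≥ 200 px and circularity in
   [0.25, 1.00]; particles larger than 1.5× the median area count as
   two touching bunches ("double-cluster" adjustment).
5. **Yield model** — per-vine cluster surface S (cm²) against measured
   yield y (g), fitted by OLS (`y = β₁S + β₀ + ε`), statsmodels-style:
   a model object whose `fit()` returns results with estimates,
   standard errors, R², `predict` and `summary`. Fit one season, apply
   to the next.
6. **Evaluation** — detection TPR (and TPR restricted to ripe
   clusters), signed percent error and accuracy = 100 − |error| for
   yield, NDVI for vigor zoning, and a ground-vs-UAV survey cost
   calculator.

A seeded synthetic scene generator renders fruiting-zone images
(foliage band, soil, compound-blob clusters, occluding leaves, dappled
shade) with exact per-pixel ground truth, so the entire chain is
testable without field data.

## Worked example

```python
from vineyield import (best_condition_preset, generate_scene, generate_vine_table,
                       PipelineConfig, detect_image, AreaYieldModel)

image, truth = generate_scene(best_condition_preset(seed=0))
result = detect_image(image, PipelineConfig(pixels_per_cm=5.0))
ps = result["particles"]
print(f"ground truth clusters : {truth.cluster_count}")
print(f"detected particles    : {ps.raw_count}")
print(f"adjusted count        : {ps.adjusted_count}")
print(f"total cluster surface : {ps.total_area_cm2():.1f} cm^2")

table = generate_vine_table(n_per_zone=10, seed=0)
print()
print(AreaYieldModel(table).fit().summary())
```

prints

```
ground truth clusters : 8
detected particles    : 8
adjusted count        : 8
total cluster surface : 133.1 cm^2

Area -> yield linear regression (OLS)
-------------------------------------
  n vines (train) : 20
  slope           : 3.4394 g/cm^2  (se 0.2010)
  intercept       : 47.4434 g
  R^2             : 0.9421
```

All eight synthetic bunches are found, none is flagged as a double, and
the regression on 20 synthetic vines (true slope 4 g/cm², 15% yield
noise) recovers the area→weight law with R² ≈ 0.94. The fitted slope of
a single noisy 20-vine season scatters around the true value; averaged
over many seeded seasons it converges to 4 g/cm².

The same stages are available from the shell:

```bash
vineyield simulate --preset best --n-scenes 3 --seed 0 --output-dir scenes/
vineyield detect scenes/scene_best_0000.png --pixels-per-cm 5 --output-dir out/
vineyield yield train_vines.csv apply_vines.csv --output-dir out/
vineyield cost 5 10 50
```

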