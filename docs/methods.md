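# Methods

This note records the models, parameter choices and numerical decisions
behind pelletmorph, and what the synthetic-data validation does and does
not demonstrate about real micrographs.

## Automated segmentation model

Bright-field pellets are dark objects with fuzzy edges on a bright,
unevenly illuminated background.  The pipeline is a fixed chain:

1. **Adaptive threshold.**  Foreground = pixels strictly below
   `local_mean − (1 − sensitivity) · SD`, where `local_mean` is the mean
   over a square window and `SD` is the global intensity standard
   deviation.  The window defaults to "auto": the largest odd integer
   ≤ ⅛ of the smaller image dimension (floor 3).  Comparing against a
   *local* mean makes the rule robust to smooth illumination gradients,
   and because both terms shift with the image, the output is invariant
   under a constant intensity offset (tested).  A perfectly uniform
   image has SD 0 and yields no foreground.  The exact statistic of
   adaptive-threshold implementations varies between environments; this
   concrete rule (mean statistic, sensitivity 0.5) is fixed here and all
   downstream numbers are reported against it.  Pellets larger than the
   window are detected as closed rims (the window sees only pellet
   interior); the hole-filling step below restores them to solid
   silhouettes — this is the role hole filling plays in the chain.
2. **Erosion** with an exact disk footprint of radius 2 px (no
   decomposition approximation).  Its purpose is separating adjacent
   pellets that merge at a thin neck.
3. **Border clearing**: components touching any image edge are removed —
   their area is censored by the frame.
4. **Hole filling**: enclosed background holes are filled.  With
   8-connected particles the complementary holes are 4-connected, so the
   fill uses the cross-shaped structure (and vice versa for 4-connected
   particles).
5. **Dilation** with a disk of radius 4 px, partially compensating the
   erosion and the conservative threshold.
6. **Size filter**: components with pixel area outside the *inclusive*
   interval [500, 60,000] are discarded.  The bounds are applied to the
   post-dilation areas, i.e. the filter is the last stage.  Survivors
   are renumbered 1..k in raster order of their first pixel so output is
   reproducible.

Areas are converted to µm² with `pixel_area_um2` (default 5.44 µm² px⁻¹,
the calibration of a 40x bright-field setup).  Connectivity is 8 for
components and border-touch tests (configurable to 4).

The stage order (threshold → erode → clear border → fill holes → dilate →
filter) is fixed; erosion before hole filling means a rim thinner than
2 px can break and lose its interior — at the default window sizes rims
are ≈ half a window thick, far above that limit.

### Manual-equivalent reference workflow

The ImageJ-style reference: rolling-ball background subtraction
(radius 2000 px, light background, no smoothing) → CLAHE (square tiles of
127 px, 256 gray levels, clip limit = max_slope/256 with max slope 3.00,
i.e. the tile histogram is clipped at 3× the uniform bin height) → global
Otsu threshold, dark foreground → connected components → keep area
≥ 2000 px ("2000–infinity", lower bound inclusive).  A rolling ball of
radius 2000 px exceeds any typical frame; at that radius the background
estimate degenerates to a constant plane, so the subtraction is computed
directly as a constant shift.  For radii smaller than the image the
exact rolling-ball filter is used.  Images smaller than the CLAHE tile
are rejected rather than silently padded.

## Morphometric statistics

Per time point, areas from all replicate images are **pooled** (not
averaged per replicate) before quantiles — every particle carries equal
weight, matching how hundreds of images per time point are analysed in
practice.  Quantiles use linear interpolation between order statistics;
the IQR depends on this choice, so it is fixed and documented.  Summaries
with n < 30 particles carry a low-n flag; empty time points stay in the
table as marker rows so time axes remain aligned.  Comparisons use
Welch's unequal-variance two-sided t-test plus paired quantiles; the
median bias (b − a at the 0.5 level) summarises systematic offset.  An
optional µm² lower-limit filter can be applied at pooling time (default
off) for workflows that post-filter small debris.

## Growth statistics

* `c_v,i` uses the **sample (n−1) standard deviation**.  Cycles with
  fewer than two non-missing replicate values are skipped and the cycle
  count m reduced; a cycle with non-positive mean raises an error naming
  the cycle, since CV is undefined there.
* **Signal onset**: the limit of detection is estimated from the pooled
  values of the first `blank_cycles` (default 5) cycles as
  mean + z₀.₉₉ · SD (one-sided normal quantile at α = 0.01); the start
  cycle is the first whose replicate mean exceeds the LOD for 3
  consecutive cycles.  The persistence requirement suppresses single-cycle
  noise triggers.  The exact LOD estimator used by any particular
  acquisition environment is not standardised; this rule is fully
  specified so results are reproducible.
* **rmcv** averages the computable c_v,i between the start cycle and the
  end of the series, inclusive.
* **Outliers**: |x − median| > 3 × 1.4826 × MAD.  The 1.4826 factor makes
  the scaled MAD a consistent σ estimate under normality.  When MAD = 0
  the rule degenerates to flagging any value off the median; an all-equal
  vector therefore has no outliers without a special case.
* **Dilution planner**: assumes backscatter ∝ biomass concentration, so
  factor = max(1, current/target) and diluent volume =
  sample × (factor − 1), with 0.9 % (w/v) NaCl as diluent.  The linear
  proportionality is an explicit modelling assumption.

## Synthetic data: what it emulates

**Scenes.**  Pellets are rendered as radially symmetric sigmoid intensity
profiles: dark core (default 60) fading through a fuzzy halo to the
background (default 200) over `halo_width_px` (default 7 px) with
softness 1 px; the background may carry a linear illumination gradient
(default amplitude 25 across the frame) and Gaussian noise (SD 5).  The
default frame is 1280 × 960 px at 5.44 µm² px⁻¹, pellet radii are
lognormal (median 20 px, log-SD 0.25), and a minimum center separation
(default 90 px) keeps pellets disjoint; separation 0 permits
touching/overlapping pellets for exercising the erosion-based
separation.  The recorded **ground-truth area of a pellet is its
halo-inclusive silhouette** (distance ≤ radius + halo width); the
core-only area is recorded alongside.  The defaults were chosen once so
that a rendered pellet resembles a 40x bright-field pellet and so that
the detection chain — which thresholds inside the halo and nets +2 px of
morphology — lands slightly *inside* the true silhouette.  On
default-condition scenes the pipeline then recovers every separated
in-range pellet, a pooled median within 10 % (typically −3 %) and IQR
within 20 % of truth, and a median never above the halo-inclusive truth:
the slight underestimation expected from core-oriented detection.

For time courses, the lognormal radius median is rescaled so the true
median silhouette area follows a caller-supplied growth function, and
the minimum separation scales with the radius median (real frames show
fewer, larger, still-disjoint pellets late in cultivation).  Per-scene
seeds derive from (base seed, target median area, scene index), so a
constant growth function reproduces byte-identical time points.

In the auto-vs-manual comparison on these scenes, the manual-equivalent
median lies above the automated one mainly because its 2000 px lower
bound truncates the small-pellet tail of the population; on matched
individual pellets the smooth sigmoid halo does not reproduce the
core-only behaviour of adaptive thresholding on real hyphal coronas.
This is a renderer limitation to keep in mind when reading that
comparison.

**Growth curves.**  Each well follows a logistic mean curve
`baseline + capacity / (1 + exp(−rate (t − t_mid)))` sampled every 10
minutes (defaults: baseline 2, capacity 100 signal units, rate 0.3 h⁻¹,
8 wells, 48 h), with `t_mid` placed so the mean exceeds the baseline by
one signal unit at `lag_h` (default 10 h) — a concrete, testable onset
definition.  Noise is i.i.d. multiplicative lognormal per (cycle, well)
with log-SD σ, so the population CV is √(exp σ² − 1) ≈ σ, and the
recovered rmcv estimates σ directly (within 20 % at σ ≤ 0.52 over 100
seeds).  Real replicate curves also carry well-level persistent offsets
and autocorrelated drift that this model omits; rmcv recovery here
validates the estimator, not the noise structure of any instrument.

**What passing tests do not show.**  The renderer has no hyphal texture,
no point-spread function or depth-of-field blur, no motion blur from
flow, and smooth circular silhouettes; real micrographs contain
irregular, partially overlapping, sometimes out-of-focus pellets.
Ground-truth recovery on synthetic scenes therefore validates the
implementation of the chain, not its accuracy on any particular
microscope's images — for those, the parameters (sensitivity, window,
radii, size bounds, pixel calibration) are exposed in `SegParams` and a
YAML config.

## Numerical and interface choices

* All randomness flows from integer seeds through numpy Generators;
  identical configs reproduce byte-identical CSV/JSON/PNG outputs
  (tested).  Cross-platform determinism holds for fixed IEEE-754 double
  semantics.
* Degenerate inputs have defined behaviour: empty masks and manifests
  pass through as empty results; empty distributions raise an explicit
  error that table builders convert into marker rows; flat images yield
  no particles in both workflows.
* Particle CSVs embed the full parameter snapshot as `#`-prefixed header
  lines; JSON summaries embed it structurally.  The CLI maps validation
  errors to exit code 2 and I/O errors to 3, and writes a provenance
  JSON (config hash, version, seed) per run.
* Problem sizes in the test-suite and acceptance script (e.g. 300–1,000
  oracle masks, ~300-particle recovery pools, 100-seed rmcv averages,
  5 scenes per time point over 14 time points) were chosen as the
  smallest sizes at which the measured quantities are stable against
  their tolerances.

## Known limitations

* The adaptive-threshold offset rule is one concrete realisation of
  "local mean with sensitivity"; other implementations will differ in
  detail, and segmentation parameters should be re-tuned per instrument.
* The manual-equivalent workflow approximates ImageJ's rolling ball and
  CLAHE via scikit-image; pixel-exact agreement with ImageJ is not a
  goal.
* Only 2-D projected area is measured — no 3-D shape, circularity or
  surface-texture descriptors, and no de-duplication of pellets stuck in
  a flow chamber across frames (an exclusion list in the manifest is the
  supported hook).
* The dilution planner assumes strict signal–biomass linearity.
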