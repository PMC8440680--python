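# Methods

This note documents the models, conventions and numerical choices behind
`ccfd`, in the spirit of a statistics-package methods appendix: what each
stage assumes, which knobs matter, and what the synthetic tests do and do
not demonstrate about real scans.

## Measurement grid

The region of interest is the annulus between fovea-centered circles of
4 mm and 6 mm diameter. A pixel belongs to the annulus iff the Euclidean
distance from its center to the fovea center, in physical units, satisfies
`inner_radius ≤ d < outer_radius`; the half-open interval prevents double
counting where concentric regions abut. At the default 20 µm/pixel the
rasterized annulus area is 15.704 mm² versus the analytic
π(3² − 2²) = 15.708 mm² (−0.03 %).

Quadrants are the four 90° sectors bounded by the two diagonal lines
through the fovea center at ±45° to the image rows — the X-shaped division
conventional for perifoveal grids. With row 0 anatomically superior, the
superior sector is Δrow < 0 with |Δcol| ≤ |Δrow|. Boundary pixels
(|Δcol| = |Δrow|) are assigned to the superior/inferior sectors, making the
four quadrants an exact partition of the annulus. Nasal/temporal naming
needs laterality; we adopt the "macula temporal to the disc" convention
(right eye ⇒ nasal is the left image half) and take it from metadata. The
superior quadrant, the one most informative for reticular pseudodrusen, is
laterality-invariant. The fovea center is metadata (default: geometric
image center); no automatic fovea detection is attempted.

## Binarization

Phansalkar thresholding is implemented directly (it is the core primitive
of the pipeline and is not available in scikit-image). Three conventions
that differ between published implementations are fixed and exposed as
configuration:

* **window** — circular, radius 15 px by default (300 µm at 20 µm/px),
  comparable to the largest individual deficits so that a window never sits
  entirely inside one;
* **border handling** — mirror padding (edge pixel repeated, the
  `symmetric` convention);
* **normalization** — fixed division by 255, never per-image min–max, so a
  grey level maps to the same normalized intensity in every image of a
  cohort.

Coefficients default to k = 0.25, r = 0.5, p = 2, q = 10 — the original
publication's values. The classification is strict (`intensity < t`); ties
are perfused. Window mean and variance are accumulated as exact integer
sums (int64 convolution) before one floating-point division, which makes
the vectorized implementation bit-identical to a per-pixel brute-force
enumeration — a property the test suite asserts on random images — and
independent of summation order. Note that a uniform image at grey level
128 has µ = 128/255 ≈ 0.50196, giving t ≈ 0.38310; the often-quoted value
0.381738 is the formula evaluated at exactly µ = 0.5.

## Morphometry

FD components are 8-connected (diagonal contacts merge, consistent with
confluent deficits) and are clipped to the ROI *before* labeling and
sizing, so quadrant metrics are additive to the ring metric. The minimum
size filter removes components with equivalent circular diameter
`2·√(area/π)` below 24 µm (≈ 452 µm² of area); we read the conventional
"smaller than 24 µm" cutoff as a diameter, since as an area it would be
sub-pixel at every realistic scale. The cutoff is configurable.

The FD size distribution is binned in equal-width log₁₀(area) bins of 0.2
decades spanning [min, max] observed area, with centers at geometric
midpoints, and fitted by unweighted least squares of log₁₀(count) on
log₁₀(center), excluding empty bins. Fewer than three occupied bins raises
an explicit underdetermined-fit error instead of returning a meaningless
line. The 0.2-decade width is a package choice; slopes are comparable only
between fits binned identically, which is how the pipeline always uses
them.

Intensity statistics (mean, SD with the n−1 denominator, excess kurtosis
m₄/m₂² − 3 from population moments, 256-bin histogram, sixth-order
polynomial histogram fit with its R²) are computed over all raw ROI pixels,
deficits included, before thresholding. A zero-variance ROI reports sd = 0
and NaN kurtosis with an explicit flag. The kurtosis convention is excess
kurtosis; published tables built with other toolchains may use the
non-excess variant, so absolute comparisons across software need care.

## Synthetic data

`generate_cc_image` emulates exactly the image statistics the pipeline
consumes: a clipped-normal speckled background, dark elliptical FD blobs
(axis-aligned, aspect ratio uniform on [1, 3], uniform random centers in
the 6 mm disc, overlaps merging into confluent regions) with areas drawn by
inverse-CDF sampling from a power law with density ∝ area^(−α) truncated to
[area_min, area_max]. Blobs are added until coverage of the disc first
reaches the target fraction; more than 10,000 placements raises a
generation error rather than silently under-covering. Identical seeds give
bit-identical images.

Defaults, chosen once for realism: background 170 ± 12 and deficits
40 ± 10 grey levels — clearly bimodal, as in high-quality scans, and
yielding ROI means (~125) and SDs (~63) on the scale reported for 6 × 6 mm
choriocapillaris imaging at 35 % coverage; α = 2.0 on
[1,000, 40,000] µm², spanning equivalent diameters ~36–226 µm, i.e. from
just above the 24 µm noise cutoff to large confluent patches smaller than
the threshold window. The empirical area-law exponent of real scans is not
established; α is a free parameter, and conclusions that depend on it
should be swept.

What the generator does **not** model: OCT speckle correlation,
decorrelation-signal physics, projection or shadow artifacts, vessel
texture in the background, or segmentation errors of the
choriocapillaris slab. Passing recovery tests therefore demonstrate the
pipeline's internal consistency — geometry, thresholding and morphometry
recover planted truth with well-separated grey levels (mean absolute error
~0.02 percentage points, versus the 3-point tolerance we consider
acceptable) — not accuracy on device data, where the threshold parameters
dominate the absolute FD % scale.

`generate_cohort` draws each subject's (baseline, follow-up) pair from a
bivariate normal with prescribed cell means/SDs and within-subject
correlation (default 0.5). The default cell means and SDs mirror published
ring/quadrant values in eyes with reticular pseudodrusen versus controls —
FD % around 36 rising to 43 in patients over five years against 32 → 35 in
controls, with the mean decorrelation signal falling — so the default
cohort carries a realistic interaction effect at the published dispersion.

## Statistics

* **Normality** — one-sample Kolmogorov–Smirnov against a normal with the
  sample's mean and SD (the common software default). Estimating the
  parameters from the data makes the p-value conservative (the Lilliefors
  caveat); it is used as a screen, not an inferential endpoint.
* **Baseline comparison** — two-sided pooled-variance Student t-test;
  Welch available by flag.
* **Repeated measures** — balanced 2 × 2 mixed ANOVA by the closed-form
  cell-means decomposition: the group effect is tested against subjects
  within groups, time and group × time against the within-subject error,
  all on (1, 2(n−1)) df. The implementation is cross-checked against an
  independent mixed-ANOVA routine in the test suite, and its interaction
  test's empirical type-I error at n = 8/group is 0.046 over 2,000 null
  simulations. Degenerate noiseless designs resolve 0/0 F-ratios to
  F = 0, p = 1 and x/0 to F = ∞, p = 0; fully constant data raise an
  error. A flag marks whether the within-group time effect is reportable
  under the convention that it is interpreted only absent between-group
  differences; the flag never changes the computation.
* **Slope/intercept comparison** — nested-model F-tests in the ANCOVA
  style: separate lines versus common slope on (1, n₁+n₂−4) df for slopes,
  common slope versus single line on (1, n₁+n₂−3) df for intercepts. The
  intercept test is always reported but is conditional on compatible
  slopes.
* **No multiple-testing correction** is applied anywhere; every p-value is
  per-comparison, and users running many metrics × ROIs should adjust
  externally if they need family-wise control.

## Problem sizes used in the checks

The repository's self-checks run at the study's own scale: 300 × 300 px
images, eight subjects per group, 2,000 null replicates for type-I
calibration, 20 seeds × 3 coverage targets for recovery, and 100 cohort
replicates for the interaction detection rate. These sizes make the whole
suite complete in well under a minute of simulation time while keeping the
Monte-Carlo standard error of the calibration estimates below 0.005.

## Known limitations

* Absolute FD % depends strongly on the threshold window radius and
  coefficients; values are comparable only within a fixed configuration
  (which is why every output embeds the configuration hash).
* One en-face image per eye-visit is analyzed; no image averaging or
  between-visit registration.
* QC metadata (signal quality index, motion score, segmentation adequacy)
  are device/grader inputs; the pipeline gates on them but cannot compute
  them.
* The ANOVA layer requires complete, balanced baseline/follow-up pairs;
  unbalanced designs are rejected rather than approximated.
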