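# ccfd — choriocapillaris flow-deficit quantification for en-face OCTA

`ccfd` quantifies flow deficits (FDs) of the choriocapillaris — the
capillary layer directly beneath Bruch's membrane — from en-face optical
coherence tomography angiography (OCTA) images, and compares the resulting
metrics between patient groups over time. It is aimed at retinal-imaging
researchers studying choriocapillaris perfusion in conditions such as
reticular pseudodrusen (RPD) and age-related macular degeneration, where FD
burden is a candidate progression biomarker.

## What it computes

Given an 8-bit en-face scan (nominally 300 × 300 pixels over 6 × 6 mm, i.e.
20 µm/pixel) with a known fovea center, the pipeline:

1. **ROI geometry** — builds the measurement grid: the annulus between
   fovea-centered circles of 4 mm and 6 mm diameter, and its four 90°
   quadrants with diagonal (±45°) boundaries. The superior quadrant is
   where RPD typically appear first; the annulus excludes the central zone
   that late-stage lesions contaminate.
2. **Binarization** — Phansalkar local adaptive thresholding. With window
   mean µ and SD σ of intensities normalized to [0, 1], the local threshold
   is `t = µ·(1 + p·e^(−q·µ) + k·(σ/r − 1))` (defaults k = 0.25, r = 0.5,
   p = 2, q = 10, circular window of radius 15 px); a pixel is an FD pixel
   iff its normalized intensity is strictly below `t`.
3. **Morphometry** — 8-connected FD components clipped to the ROI, with
   components of equivalent circular diameter `2·√(area/π)` below 24 µm
   discarded as noise. Per ROI it reports the FD count, the total FD area
   as a percentage of the ROI (FD %), a log-binned power-law fit of the FD
   size distribution `log₁₀(number) = m·log₁₀(area) + c`, and grey-level
   statistics (mean, SD, excess kurtosis, 256-bin histogram with a
   sixth-order polynomial fit).
4. **Group statistics** — Kolmogorov–Smirnov normality screening, two-sided
   unpaired t-tests at baseline, a balanced 2 (group) × 2 (timepoint)
   repeated-measures ANOVA with the group × time interaction, nested-model
   F-tests comparing regression slopes and intercepts between the four
   group × time cells, and percent-change summaries.

Because clinical OCTA scans are rarely shareable, `ccfd.synthetic`
generates seeded en-face images with ground-truth FD masks (power-law blob
areas, confluent overlaps, well-separated grey levels) and seeded cohort
tables with prescribed group × time effects, so the entire pipeline is
testable end to end without patient data.

## Worked example

```python
from ccfd import (ImageSynthesisParams, generate_cc_image, build_ring_mask,
                  build_quadrant_mask, phansalkar_threshold,
                  extract_flow_deficits, fd_metrics, fit_size_distribution,
                  intensity_stats)

bundle = generate_cc_image(ImageSynthesisParams(seed=42, target_fd_fraction=0.36))
image = bundle.image
ring = build_ring_mask(image)                    # 4-6 mm annulus
sup = build_quadrant_mask(ring, image, "superior_quadrant")
fd_map = phansalkar_threshold(image)             # Phansalkar defaults

for roi in (ring, sup):
    fds = extract_flow_deficits(fd_map, roi)     # 24 um minimum size
    m = fd_metrics(fds)
    fit = fit_size_distribution(fds)
    ist = intensity_stats(image, roi)
    print(f"{m.roi_kind}: FD% = {m.fd_percent:.2f}, count = {m.fd_count}, "
          f"m = {fit.m:.3f}, c = {fit.c:.3f}, mean = {ist.mean:.1f}, "
          f"sd = {ist.sd:.1f}, kurtosis = {ist.kurtosis:.2f}")
```

prints

```
ring: FD% = 34.71, count = 514, m = -0.677, c = 4.200, mean = 124.8, sd = 62.9, kurtosis = -1.51
superior_quadrant: FD% = 32.20, count = 150, m = -0.692, c = 3.687, mean = 128.3, sd = 61.9, kurtosis = -1.35
```

The recovered ring FD % (34.71) agrees with the generator's ground truth
inside the same annulus (34.72 %) to 0.01 percentage points — the
binarization is recovering the planted deficits, not an artifact of the
threshold. The negative slope `m` says small deficits outnumber large
ones; a flatter slope and lower intercept indicate a shift toward fewer,
larger, confluent deficits, the signature reported in diseased eyes.

## Command line

```sh
ccfd synth-image  --config image.yaml --out outdir/        # image + truth mask
ccfd synth-cohort --config cohort.yaml --out cohort.csv
ccfd run  --config study.yaml --images imgdir/ --meta meta.csv --out results/
ccfd stats --metrics results/metrics.csv --out report.json
```

`ccfd run` applies the quality gates (signal quality index ≥ 7,
motion-artifact score ≤ 2; missing QC fields exclude the eye explicitly),
analyzes every passing eye for the ring and superior quadrant, writes a
per-eye metrics CSV and a statistics JSON, and embeds the configuration
hash and seed in every output. Reruns are byte-identical.

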