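# Methods

## Model

`stainquant` treats a bright-field well scan as three co-registered
single-channel transmission images, one per LED illumination colour
(red 623 nm, green 523 nm, blue 460 nm on typical plate imagers).  Under
narrow-band illumination, transmitted intensity is taken as linear in the
pixel value, so the relative amount of dye at a pixel is captured by the
quotient of the dye's signal channels over its complementary channels:

    ratio(p) = Σ_{c ∈ signal} I_c(p) / Σ_{c ∈ complement} I_c(p)

A pixel is dye-positive when `ratio(p) ≥ t` with an inclusive threshold
`t` (1 for the red dyes Alizarin Red S and Oil Red O, 4 for Alcian Blue
8GX).  The complement aggregation is the **sum** of the complement
channels, not their mean; the thresholds are stated on that scale (a
ratio of 1 over the summed cyan channels means the red signal is twice
the *average* of green and blue).  The measurement per well is the count
of positive pixels inside the region of interest, with the area fraction
(count / ROI pixels) and the physical area (count × pixel_size_µm²)
reported alongside.

Key consequences of the ratio form, both enforced by tests:

* **Scale invariance.** The statistic is homogeneous of degree zero, so
  a global intensity rescaling (bit depth, exposure, illumination gain)
  leaves every classification unchanged.
* **Monotonicity.** Raising a signal channel can only keep or gain
  positivity; raising a complement channel can only keep or lose it
  (among pixels with a defined ratio).

## Numerical choices

* **Float promotion.** Channel planes are converted to float64 before
  any arithmetic.  Sums of two 16-bit values reach 131,070 and would
  clamp in 16-bit integer arithmetic; `ratio_map` refuses unpromoted
  composites rather than silently saturating.
* **Zero denominators.** A pixel with zero summed complement intensity
  has no reliable ratio (no transmitted complementary light).  It is
  flagged in `undefined_mask` and excluded from positivity; no inf/NaN
  propagates.
* **Pixel-in-disc rule.** A pixel (i, j) belongs to a circular ROI iff
  its center (j + 0.5, i + 0.5) lies within the radius.  This makes
  rasterized discs unambiguous and exactly reproducible.
* **Stitching.** Tile grids are stitched row-major, origin top-left,
  with overlap_px = round(overlap_µm / pixel_size_µm), ties away from
  zero.  The default overlap policy is *overwrite* (the later tile in
  row-major order wins), which makes stitching the exact inverse of
  overlap-respecting cropping and hence testable bit-exactly; a
  *crop-half* policy (overlap split evenly) is available.  Vendor
  grid presets: 9 × 13 tiles per 24-well-plate well, 7 × 10 per
  48-well-plate well, overlaps 200 µm (x) and 250 µm (y).  Tile pixel
  dimensions and the camera pixel size are instrument-specific and must
  come from user configuration.
* **Otsu thresholding.** Well detection and spheroid segmentation use
  Otsu's between-class-variance criterion on the channel-sum image
  (512-bin histogram).  The implementation returns the upper *edge* of
  the optimal threshold bin, so the dark class is exactly
  `values < threshold`; a bin-center convention can misassign a whole
  intensity level that sits above its bin center, which matters for the
  spiky histograms of flat synthetic fixtures.
* **Well detection.** Bright pixels above the Otsu threshold are
  hole-filled (stained regions absorb light and can dip below the cut),
  the largest connected component is taken, and its centroid and
  equivalent-area radius define the circle.  Detection fails loudly when
  the radius is outside a configurable tolerance of the expected well
  radius; a manually configured circle always overrides detection, since
  fixed acquisition geometry implies fixed ROIs.
* **Spheroid segmentation.** Tissue is the below-threshold (absorbing)
  class; holes are filled and the largest component kept.  Sections are
  pooled as Σ positive / Σ spheroid pixels — pixel-weighted, not the
  unweighted mean of per-section fractions.

## Scoring and statistics

* **Ranking Points.** Per cell line and lineage, the replicate means at
  each timepoint (days 14, 17, 21 by default) are summed, then divided
  by 1000 for image-based values or multiplied by 1000 for absorbance
  optical densities.  Both scalings are pure presentation factors; the
  induced ranking is invariant under any strictly increasing transform.
  Replicate means (not replicate-level sums) enter the sum by default.
  Control wells are excluded from the score by default; an optional
  switch subtracts the per-timepoint control mean (floored at 0) before
  summing.  Absorbance blanks, when present, are subtracted first and
  floored at 0.
* **Measured value.** The value entering Ranking Points defaults to the
  positive pixel count; area fraction or µm² area can be selected by
  configuration, since either is a defensible per-well measurement and
  the ranking is unaffected when ROI sizes are equal.
* **Ties.** Ranks are a permutation of 1..n within a lineage; exact ties
  are broken lexicographically by line name and flagged.
* **Comparison statistics.** The assay signal-to-noise ratio is the mean
  of differentiated wells over the mean of undifferentiated controls
  (infinite and flagged when the control mean is zero with positive
  signal).  Pearson's r between image-based and absorbance scores is
  computed from the closed form and cross-checked against
  `scipy.stats.pearsonr` in the test suite.
* **Dispersion.** Reported spread is the sample standard deviation
  (ddof = 1), undefined (NaN) for single replicates.

## Synthetic data generator

The generator renders the geometry of a stained whole-well scan: a
bright circular well disc (default intensity 45,000 of 65,535) on a
darker plate background (18,000), flat-top stained discs whose channels
are mixed toward levels that realise a chosen target ratio (with an
optional linear edge falloff whose pixels may straddle the threshold),
dirt discs that scale the channels by per-channel hue factors (neutral
hue preserves every ratio, so neutral dirt can never become positive),
and additive per-channel Gaussian noise, clipped to the valid range.

The ground-truth mask is derived from the *noiseless, integer-rounded*
image by a plain per-pixel Python loop that re-implements the ratio rule
independently of the production classifier; the two implementations
cross-validate each other in the test suite.  Noise is applied after
truth derivation, so the truth is exact by construction for every
(spec, seed).

What the generator does **not** emulate: cell texture, optics and
point-spread blur, illumination gradients and vignetting, meniscus edge
artifacts, and chromatic registration error.  Passing tests therefore
demonstrate the correctness of the counting machinery and its
noise/debris robustness on idealised geometry — not the biological
validity of the thresholds on real tissue, which rests on the underlying
staining chemistry.

Simulated time courses draw replicate values as
`rate × day × (1 + N(0, σ_rel))`, floored at 0, with the true ranking
defined by `Σ rate × day`.  The default acceptance conditions use six
lines with well-separated accumulation rates (30–400 counts/day, nearest
pair 30% apart), three replicates, and days {14, 17, 21}; σ_rel = 0.05
models the replicate scatter of a well-behaved assay.  Problem sizes in
the routine checks (512 × 512 wells, 20 seeded replicates, 100 ranking
seeds, 40 px tiles for stitching round trips) were chosen as the
smallest sizes at which every geometric feature — well rim, multiple
spots, falloff bands, debris — is still well resolved.

## Known limitations

* The ratio thresholds assume narrow-band LED illumination; broadband
  white-light images violate the linearity assumption behind the ratio.
* Co-localized dyes are not separable (no colour deconvolution — a
  deliberate non-goal).
* Well detection assumes one well per image and a bright well on a
  darker surround; spheroid segmentation assumes one dominant section
  per image on a bright background.
* The ROI radius relative to the physical well wall is a user choice;
  no default rim exclusion is claimed.
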