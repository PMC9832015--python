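# Methods

This note records the models, conventions and parameter choices behind
`seedmorph`, and what the synthetic data does and does not establish
about behaviour on real photographs.

## Segmentation model

The imaging stage assumes chroma-key photographs: seeds spread without
overlap on a uniformly coloured blue background, a solid scale tag of
known physical length (default 16 mm) somewhere in the frame, shadows
suppressed by the acquisition rig rather than by software. Under these
assumptions segmentation is a per-pixel colour problem:

* **Calibration.** The tag is found as the unique connected region
  matching the tag colour within a Chebyshev tolerance (0 by default —
  exact match, appropriate for synthetic scenes; raise it for real
  photographs). mm/px is the tag's physical length divided by its
  horizontal pixel extent, so a tilted tag would bias the scale; the
  tag is assumed axis-aligned.
* **Channel and polarity.** Thresholding acts on the blue channel with
  foreground *below* the threshold: a blue background is bright in
  blue, seeds of essentially any natural colour are dark there. Both
  the channel and the polarity are parameters.
* **Threshold.** Otsu's criterion (maximal between-class variance over
  the 256-bin histogram) by default, a fixed threshold as fallback for
  difficult lighting. A constant channel raises an error rather than
  guessing.
* **Labeling.** 8-connected components (the common particle-analysis
  convention; 4-connectivity available), labels in raster-scan order.
* **Noise removal.** Threshold = median particle area / `size_ratio`
  (default 100), computed once over the pre-filter particles. The
  median, not the mean, so that the specks being removed cannot drag
  the estimate of "seed size"; a single pass, no iteration. Particles
  touching the tag's bounding box are excluded beforehand.

Touching-seed splitting (watershed) is deliberately out of scope: the
acquisition protocol spreads seeds manually without contact.

## Shape descriptors

For a particle with `n_px` pixels at scale `s` mm/px:

| quantity | definition | default |
|---|---|---|
| area `A` | `n_px · s²` | — |
| width, height | axis-aligned bounding-box extents (inclusive) | — |
| perimeter `P` | weighted boundary chain: axis steps 1, diagonal steps √2 | `chain` |
| major axis `M` | `4·sqrt(λ_max)` of the pixel-coordinate covariance | — |
| circularity | `min(1, 4πA/P²)` | — |
| roundness | `min(1, 4A/(πM²))` | — |

Width/height use the axis-aligned box, not the rotated minimum-area
rectangle; the two conventions differ for tilted seeds and the
axis-aligned one is the pixel-grid standard. The major axis is the
moment-equivalent-ellipse convention (no fitting); on a filled ideal
ellipse it recovers `2a` to well under 2% for semi-axes ≥ 10 px, and
roundness then equals the axis ratio `b/a`.

**Perimeter bias.** The chain estimator is exact on axis-aligned
rectangles (a 10×10 px square measures 36 px) but overestimates smooth
contours — a digitized line at angle θ measures `cosθ + (√2−1)sinθ`
times its true length, up to +8% at 22.5° and about +5% averaged over
a circle. Digital circularity under the chain convention therefore
saturates near 0.91 rather than 1.0 for large circles. Since the
descriptors are used comparatively (variance within and among
accessions), a consistent bias is acceptable; where absolute
circularity matters, `method="crofton"` (4-direction Crofton formula)
is nearly unbiased on smooth blobs (circularity ≥ 0.99 at r = 100 px)
at the cost of no longer being exact on rectangles. Both descriptors
are clamped at 1.0, and particles under 50 px trigger a warning —
digital shape measures are not trustworthy at that size.

Degenerate conventions: a single pixel has perimeter `4s`; the major
axis requires ≥ 2 pixels with nonzero coordinate variance.

## Statistics stage

* **QC.** Records with any feature exactly 0 are removed first; then
  records where any length/area feature exceeds `outlier_ratio`
  (default 10) times that feature's global median. The ratio rule
  codifies the kind of ad-hoc removal a practitioner would do by eye —
  a 99 mm "seed" against a 5.7 mm median is a merged-row artefact, not
  a seed — while sitting far above biological variation.
* **Normality screening.** Shapiro–Wilk per (accession, feature); an
  accession fails when any feature has p < α (default 0.05, no
  multiple-testing correction by default — the screen is descriptive,
  flagging accessions for inspection, not a confirmatory test; note
  that with 5 features per line the family-wise null failure rate is
  well above α, around 15–20% for dependent features at n ≈ 95).
  Accessions with < 3 records or constant features are flagged
  untestable and excluded from failure counts.
* **Medians.** Per-accession medians (midpoint convention) feed the
  clustering; medians rather than means for robustness against
  residual segmentation artefacts.
* **k-means.** Lloyd iteration with k-means++ seeding, best of 10
  restarts under a deterministic seed schedule, convergence at an
  assignment fixed point or 300 iterations; empty clusters are
  reseeded to the farthest point. Features are z-scored by default
  (mm² and dimensionless ratios are incommensurate; a raw mode exists
  for clustering unscaled medians). Distortion is the sum of squared
  distances to assigned centroids and is recorded per iteration — it
  never increases within a run.
* **Elbow selection.** The distortion curve is computed for
  k = 1..k_max with the same restart seeds for every k, plus one
  warm-start candidate per k built from the best (k−1)-solution's
  centroids augmented with the farthest sample; the warm start makes
  the curve provably non-increasing in k. The elbow is the interior k
  maximizing the discrete second difference `D(k−1) − 2D(k) + D(k+1)`,
  ties to the smallest k — a deterministic, testable formalization of
  choosing the kink by inspection. Note this rule compares curvature
  on the absolute scale, so it finds the planted k when cluster
  separations are of comparable magnitude; on hierarchically
  structured data it reports the dominant coarse split, which is the
  honest answer for such data.
* **KDE.** Gaussian kernel, Scott's bandwidth `h = σ·n^(−1/5)` by
  default (fixed-h override), evaluated on 256 points spanning the
  data range padded by 3h; the density integrates to 1 on that grid
  within 1% and its values may exceed 1 on narrow supports.
* **Correlations.** Spearman's ρ with midrank ties and two-sided
  t-approximate p-values, on the per-line medians — rank-based because
  the per-line distributions do not pass normality screening. Pairs
  involving a constant feature are reported as missing.

## Synthetic data: what it emulates

The generator reproduces the statistical shape of a real gene-bank
screening campaign:

* ~507 accessions; seeds per accession drawn as
  `round(clip(N(94.7, 35), 41, 238))` (mean ≈ 95);
* per-accession trait distributions unimodal and approximately normal
  (truncated positive), within-accession coefficient of variation 5%;
* accessions grouped into 6 planted morphs. The default centers sit on
  a regular 5-simplex around a buckwheat-like base
  (area 20 mm², width 4.5 mm, height 5.67 mm, circularity 0.72,
  roundness 0.62) with relative spreads (0.55, 0.30, 0.30, 0.25,
  0.30), giving six *equally dissimilar* morphs — the configuration in
  which "6 planted clusters" is unambiguous. The simplex construction
  has equal per-coordinate variance, so z-scoring preserves the
  equidistant geometry. Accession centers jitter around their morph
  with 1% relative sd, yielding a between-center / within-cluster
  separation ratio ≈ 11 in standardized space;
* injectable defects: records with a zeroed feature, and a gross
  height outlier at 17.5× the mean (≈ 99 mm against a 5.7 mm mean);
* scenes: non-overlapping filled ellipses (semi-axes from a truncated
  normal, orientation uniform) in a dark brown (80,50,30) on blue
  (40,60,200) palette with a white 16 mm tag; placement by bounded
  rejection sampling (500 retries per seed) with conservative
  bounding-circle spacing. Ellipses are the default shape because
  analytic area, extents, perimeter (Ramanujan) and axis-ratio oracles
  exist for them.

What it does **not** emulate: lighting gradients, shadows (beyond a
crude optional darkened ring), seed texture, specular highlights,
touching seeds, camera distortion or colour-calibration drift. Passing
the synthetic suite therefore establishes the correctness of the
algorithms under the stated acquisition assumptions, not robustness to
violations of them; on real photographs the colour tolerance, channel
choice and threshold method are the knobs to revisit.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
data: one 1400×1800 px scene with 95 seeds (segmented in ~1 s), a
507-line / ~48k-record trait table (analysed end to end in ~2 s), and
small closed-form fixtures elsewhere. All randomness flows through
`numpy.random.default_rng` with explicit integer seeds; identical
seeds give bit-identical images, tables and cluster assignments.

## Known limitations

* The chain-perimeter bias makes absolute circularity values
  convention-dependent (see above); compare circularities only within
  one perimeter convention.
* mm/px calibration uses the tag's horizontal extent only and assumes
  square pixels and an axis-aligned tag.
* The elbow rule needs at least 3 curve points and reports coarse
  structure on hierarchical data.
* Shapiro–Wilk p-values for n > 5000 fall back to scipy's
  approximation regime; per-accession counts here (≤ 238) are far
  below that.
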