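# Methods

`dropletquant` quantifies protein condensates (liquid–liquid phase
separated droplets) in fluorescence micrographs. It implements four
analysis stages — particle segmentation with equivalent-sphere volume
statistics, bead-based two-channel registration, distance-criterion
colocalization, and per-condition ANOVA — together with a synthetic
image generator that provides ground truth for every stage. This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Segmentation and volume model

Droplets appear as bright, quasi-circular particles on a dark
background. Segmentation is classical global thresholding followed by
connected-component particle analysis:

- **Automatic threshold.** Default is Otsu's criterion evaluated
  exactly: the between-class variance `w_bg·w_fg·(μ_bg − μ_fg)²` is
  maximized over every integer intensity level in the image's range
  (computed with cumulative histogram sums, so the scan is exact and
  O(levels)). Foreground is *strictly above* the threshold; ties go to
  background; the lowest maximizer wins on ties. The iterative
  intermeans (IsoData) method — the historical default family of common
  particle-analysis software — is available as an alternative for
  fidelity comparisons. A constant image raises
  `DegenerateHistogramError` rather than returning an arbitrary level.
- **Particles.** Components under 8-connectivity (4-connectivity
  configurable). Components of ≤ 4 pixels are discarded as artifacts;
  survivors have area ≥ 5 px. Interior holes are filled *before*
  measurement, so a large droplet with smaller droplets visible inside
  it is measured as one entity.
- **Circularity** is `4π·area/perimeter²` with the perimeter from the
  standard chain-approximation; discretization can push it slightly
  above 1 for small disks, so the value is reported unclamped and
  consumers should treat 1 + ~0.1 as the practical ceiling.
- **Equivalent-sphere volume.** Assuming a completely spherical
  condensate whose great-circle disk has the measured projected area
  `A`, the radius is `r = √(A/π)` and the volume `(4/3)πr³`, reported
  in µm³. The per-image statistic is the mean of particle volumes; an
  image with zero particles has an explicitly undefined mean (`None`)
  and is excluded from volume statistics with the exclusion visible to
  the caller, rather than silently contributing a zero.

## Channel registration

A dual-view emission splitter images the green (eGFP) and red (mCherry)
bands onto one camera, leaving a small planar misalignment between the
channels. The transform is calibrated from a broad-spectrum fluorescent
bead pair visible in both channels:

1. **Bead localization** — Otsu-thresholded local maxima refined by the
   intensity-weighted centroid of a 7×7 px window after local background
   subtraction (beads are diffraction-limited at 114.17 nm pixels, so
   the spot spans a few pixels); detections closer than a minimum
   separation are merged.
2. **Matching** — mutual nearest neighbours within a distance gate;
   no point joins two pairs.
3. **Estimation** — least squares in one of three families:
   `translation` (closed-form mean displacement), `similarity`
   (scale·rotation + translation; the default, matching the rigid
   optical geometry) or `affine`. Collinear input raises an error for
   affine. Fit quality is reported as the 2-D residual RMS; with
   per-axis coordinate noise σ on one side of n = 20 pairs the expected
   residual RMS is ≈ σ√2·√(1 − p/2n) ≈ 1.3–1.4 σ, which the tests
   check against the [0.5 σ, 1.5 σ] band.

Quantification transforms droplet *coordinates*, never pixels; bilinear
image warping is provided only for overlay visualization.

## Colocalization

Droplet centers are extracted per channel (segmentation → hole fill →
moments-ellipse center, which for the filled masks coincides with the
centroid). Particles with circularity below 0.8 are excluded, an
automated surrogate for discarding deformed, non-circular droplets; an
optional overlap-exclusion mode drops particles whose dilated bounding
boxes touch. Externally supplied center lists (CSV) bypass segmentation
entirely, so manually annotated regions of interest can be classified
through the identical distance-criterion path.

Classification computes the full green×red Euclidean distance matrix in
the registered frame and accepts pairs with distance **strictly below
500 nm** (configurable) greedily in ascending distance order,
one-to-one: each droplet joins at most one heterotypic entity, which
keeps the three classes disjoint and their percentages closed
(heterotypic + green-only + red-only = 100). A pair at exactly the
criterion distance is two homotypic droplets. Each heterotypic pair
counts once in the denominator. Percentages are computed per field of
view and aggregated as mean ± sample sd (ddof = 1) *across fields*,
never pooled over particles; the pooled particle count is reported
separately.

The greedy rule is one of several defensible resolutions when several
candidates fall inside the criterion; with droplet spacings well above
the criterion (the regime both the real samples and the simulator
occupy) it coincides with the optimal one-to-one matching, which the
tests verify against exhaustive enumeration on small instances.

## Condition statistics

Per-condition comparisons of per-image counts and mean volumes use
one-way fixed-effects ANOVA (F from between/within sums of squares)
plus all pairwise two-sample comparisons re-using the pooled
within-group variance and its full degrees of freedom — the classical
"means comparison" — with Bonferroni adjustment
`p_adj = min(1, m·p_raw)` over the `m` pairs and the conventional
significance flags (\*\*\* < 0.001, \*\* < 0.01, \* < 0.05, ns).
A Welch/Satterthwaite variant of the pairwise tests is available for
heteroscedastic data. The disassembly contrast compares a
before/after condition pair on both counts and volumes (Bonferroni over
the two family members) and summarizes the direction: dissolution that
preferentially removes small droplets shows a significant count
decrease together with an *increase* in surviving mean volume.

## Synthetic data: what it emulates

The generator is the benchmark's ground truth, so its defaults are the
study conditions and are not tuned per test:

- **Composition** — droplet labels i.i.d. heterotypic / green-only /
  red-only with default probabilities 0.447 / 0.122 / 0.431, the
  measured partition of a mixed α-synuclein–S100A9 droplet population.
  Heterotypic droplets share one center in both channels (perfect
  colocalization); exclusive droplets have exactly zero intensity in
  the other channel.
- **Geometry** — radii log-normal. Wide-field statistics mode: median
  1.5 µm, log-sigma 0.4, at 325 nm pixels on 500×500 px fields, thirty
  images per condition, Poisson-distributed counts per image (mean 60).
  Two-channel TIRF mode: median 500 nm, log-sigma 0.3 at 114.17 nm
  pixels, 1024×1024 px fields, 420 droplets per field over six fields
  (≈ 2,500 particles per study). Droplet number density and intensity
  scales are not published quantities; they were fixed once at values
  giving realistic TIRF-like signal-to-noise and are configurable.
- **Placement** — uniform with every droplet fully inside the field and
  pairwise center separation ≥ 2× the largest sampled radius (rejection
  sampling), so ground-truth identity is unambiguous; an over-dense
  request raises a placement error naming the achieved count.
- **Rendering** — each droplet is a uniform disk at its plateau
  intensity (pixel coverage from 4× supersampling), optionally
  multiplied by smoothed speckle to emulate unevenly filled droplets
  (off by default); red centers are first mapped through the configured
  channel misregistration. The expected photon image is blurred with an
  isotropic Gaussian PSF (default σ 150 nm), a constant background
  added (default 20 photons/px), Poisson shot noise drawn, Gaussian
  read noise added (default sd 2), and the result rounded and clipped
  to 16 bits with the clipping fraction recorded in image metadata.
  Droplets pushed past the field edge by the transform are cropped and
  flagged in the truth record.
- **Coordinates** — x = (column + 0.5)·pixel size, y = (row + 0.5)·
  pixel size, origin at the top-left pixel corner, all distances in nm.
- **Determinism** — every generator is a pure function of its seed and
  parameters; multi-image sets derive per-image seeds from the master
  seed via `numpy` seed sequences.

What passing the synthetic benchmarks does **not** show: robustness to
uneven illumination, out-of-focus light, droplet overlap and fusion
intermediates, autofluorescent debris, or the subjectivity of manual
ROI annotation — real micrographs contain all of these, and the
published percentages derive from manually drawn ROIs that automated
segmentation only approximates.

## Misregistration sensitivity: a geometric note

With perfectly co-centered heterotypic droplets and the strict 500 nm
criterion, a *pure translation* misregistration smaller than the
criterion is undetectable by construction — every true pair moves to
the translation distance, still inside the criterion. A misregistration
only biases the heterotypic percentage once its local displacement
exceeds the criterion somewhere in the field. The end-to-end
sensitivity benchmark therefore uses a realistic dual-view
misregistration with a 300 nm translation **plus a 0.5° rotation**,
whose displacement grows across the field and unmatches a large
fraction of true pairs (recovered heterotypic share drops from ~44% to
~11%); bead-estimated similarity correction restores recovery to within
a fraction of a percentage point. The same rotation/scale magnitudes
are used in the registration recovery benchmarks (rotation 0.5°, scale
1.01, coordinate noise 0.05 px).

## Numerical choices and degenerate inputs

- Thresholding a constant image, estimating a transform from < 3
  matches or collinear points, aggregating only empty fields, and ANOVA
  on identical zero-variance groups all raise typed errors instead of
  returning conventional values.
- Empty masks and empty images yield empty particle lists; empty
  classifications carry explicitly undefined (`None`) percentages.
- Transform inversion/composition are exact linear algebra; round trips
  hold to < 1 nV (10⁻⁹ nm) in the tests.
- Significance stars use strict inequalities at 0.001/0.01/0.05.

## Known limitations

- Volume is inferred from projected area under a perfect-sphere
  assumption; acquisition (TIRF evanescent depth, PSF broadening,
  thresholding) biases apparent areas, and no correction is attempted.
- No flat-field correction, deconvolution, nonlinear (spline) channel
  distortion, or intensity-based colocalization (Pearson/Manders).
- The greedy matching can differ from a globally optimal assignment in
  pathological high-density geometries far outside the simulated and
  measured regimes.
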