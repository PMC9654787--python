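# Methods

## Effective pixels and rate indices

A pixel is *effective* when its intensity strictly exceeds a threshold
in all three channels (probe, pFAK, Rab5). The default threshold is 0 —
the literal "positive in all three colors" rule — which is exact on
zero-background synthetic images but degenerate on real micrographs,
where any nonzero camera offset makes most pixels "positive"; the
threshold is therefore a first-class parameter of every operation, not
a hidden constant. The same strict `>` rule defines the single-channel
counts N_R (pFAK), N_G (Rab5) and N_B (probe) over the whole frame, and
the rate indices N₀/N_R, N₀/N_G, N₀/N_B. A rate with a zero denominator
is reported as a flagged missing value (`None`/NaN), never coerced to 0
or 1.

Pairwise colocalization is reported as both Pearson correlation over
in-scope intensity pairs and Manders overlap coefficients (fraction of
one channel's intensity in pixels where the partner exceeds its
threshold), in explicitly labeled columns: published "colocalization
coefficients" frequently mean either one, so the package computes both
rather than guessing. Pearson is flagged undefined on zero variance;
Manders on zero total intensity.

Line profiles sample the digital (Bresenham) line between two pixels,
endpoints inclusive, without interpolation, so profile values are raw
grid integers and exactly reproducible.

## Colocation islands

Islands are maximal connected components of the effective mask.
Adjacency defaults to 8-connectivity — diagonal contact counts, which
matches how punctate blobs read visually — with 4-connectivity
available; neither choice is canonical, so both are exposed. Island ids
are assigned in raster-scan order of each component's first pixel
(components are explicitly re-ordered by first flat index, so labeling
never depends on the labeling library's internals). No minimum island
size is applied by default; `min_size` is available for noise
robustness. Per-island statistics (means, maxima, centroid) are
computed over member pixels only, and `island_surface` returns the
bounding-box crop of all three channels plus the membership mask for
per-endosome intensity surface plots.

## The quadratic intensity model

At effective pixels the pFAK intensity is modeled as a quadratic in the
probe intensity,

    N_pFAK = a0 + a1 * N_probe + a2 * N_probe**2 ,

fit by ordinary least squares on the Vandermonde design (1, x, x²). The
reference coefficients are (125.86, 0.346, −2.99×10⁻⁵). The quadratic
reading of the last term is itself a design decision: the source
expression is typographically ambiguous about the exponent, and a
second linear term of order 10⁻⁵ alongside 0.346 would be redundant,
whereas a quadratic term places the curve's vertex near 5,800 — just
above a 12-bit intensity range, which is plausible for confocal data.
`--degree 1` forces a straight-line fit for the other reading.
Intensities are treated as unitless confocal counts and are not
normalized, so the fit is scale-agnostic. Requirements: at least
degree + 1 pairs with that many distinct abscissae, otherwise the
rank-deficient design is rejected with an explicit error.

Inference is non-parametric throughout. Coefficient standard errors
come from a case-resampling bootstrap (default 200 resamples;
rank-deficient resamples are redrawn). The positive-correlation claim
is tested by permuting the pFAK values against the probe values
(default 9,999 permutations, seeded), with the one-sided p-value
(1 + #{r_perm ≥ r_obs}) / (B + 1); a parametric t-test on r would
overstate the evidence because pixels within one punctum are spatially
dependent.

### Fitting unit in the pipeline

`extract_pairs` yields one pair per effective pixel. The end-to-end
pipeline, however, defaults to `fit_unit = "island_max"`: one
(max-probe, max-pFAK) pair per colocation island. Under the generative
spot model both channels of a punctum share the same spatial kernel, so
a raw pixel pair is (k·P, k·Q) for a kernel factor k ∈ (0, 1]: the
linear coefficient survives pooling over k, but the intercept is
attenuated and the curvature inflated, conflating optics with the
peak-level coupling. The island maximum estimates the punctum peak
directly and recovers all three coefficients. Pixel-level
(`fit_unit="pixel"`) and island-mean pairing remain available.

## Synthetic micrographs

The generator emulates the stated acquisition geometry: 512 × 512 px
frames, 12-bit intensities (the quadratic vertex near 5,800 rules out
8-bit; 12-bit is the common confocal depth), punctate signal in three
channels. Per image:

- punctum count ~ Poisson(`n_puncta`, default 40 — a typical endosome
  count per cell section); radii uniform in 2–5 px;
- centers uniform on the integer pixel grid with enough margin that the
  rendered spot fits the frame. Snapping centers to the grid means each
  punctum's peak intensity is realized exactly at one pixel, so peak
  intensities are recoverable from the image — the property the
  island-max fitting unit relies on;
- channel membership multinomial: `f_triple` = 0.6 of puncta carry all
  three channels, two-channel fractions (probe+pFAK 0.1, probe+Rab5
  0.1, pFAK+Rab5 0.05) and the remainder split equally over single
  channels;
- probe peaks uniform on [200, 4000] (the true intensity distribution
  is unknowable from published text; this spans most of the 12-bit
  range and is configuration, not a claim about real cells); Rab5 peaks
  independent, same default range;
- for puncta carrying both probe and pFAK, the pFAK peak is the
  quadratic coupling of the probe peak plus Gaussian noise (sd 20),
  clipped to [1, 4095] — a punctum that is a member of a channel is by
  definition detectable there;
- each punctum renders as an isotropic Gaussian spot, sd = radius / 2,
  truncated at 3 sd (a standard PSF surrogate; no Airy optics or shot
  noise), channels add where puncta overlap, then optional constant
  background and Gaussian background noise are added and the result is
  clipped and rounded to integers.

Overlap is allowed by default; `min_spacing` enforces center separation
for tests that need puncta to stay distinct islands (e.g. island count
= triple-punctum count, or n₀ = 0 exactly when `f_triple` = 0 with zero
background). All randomness flows from one seed: the dataset generator
draws one sub-seed per image (recorded in the manifest), and within an
image a single generator serves punctum sampling then noise, so every
artifact is byte-reproducible.

What passing tests on these images do *not* show: robustness to real
backgrounds, bleed-through, chromatic misregistration, non-Gaussian
PSFs or cell-shaped intensity structure — none of which the generator
models.

## Group comparison and report utilities

`compare_groups` contrasts a rate index between two runs by the
difference of per-image means with a two-sided permutation test over
image labels (seeded; p undefined when a group has fewer than 2
images). It is labeled a permutation test because the original
comparisons report significance without naming their test.
`fold_change(value, baseline)` is the plain ratio used for absorbance
gain reporting (0.31 / 0.0027 ≈ 115).

## Numerical and testing choices

- Coordinates are (row, col), 0-based, row 0 at top, everywhere.
- TIFF round-trips write one page per channel in (probe, pFAK, Rab5)
  order; PNG uses blue = probe, red = pFAK, green = Rab5; a JSON
  sidecar carries the declared bit depth (12-bit data live in a 16-bit
  container) and provenance label. Explicit `channel_map` overrides any
  convention on read.
- Determinism: identical run configurations produce byte-identical
  reports; the output directory is excluded from the configuration hash
  since the numbers cannot depend on it.
- Test oracles are deliberately primitive: triple-loop pixel counting,
  BFS flood fill, hand-computed four-point Pearson values — independent
  of the vectorized implementation paths they check. Property suites
  (hypothesis, derandomized, plus 200 seeded fuzz cases) cover the
  counting bounds, threshold monotonicity, island-size conservation and
  Pearson affine invariance.
- Problem sizes used in the test suite: parameter-recovery checks use
  10,000 simulated pairs with 120–200 bootstrap resamples and 50
  replicates; the end-to-end check uses the default 22-image, 512×512
  dataset; oracle equivalence uses 100 random images up to 64×64.
  These sizes give stable statistics while keeping the suite fast.

## Known limitations

- The strict `> 0` rule is only meaningful after background handling,
  which the package intentionally leaves to the user (no Costes
  thresholding, deconvolution or spectral unmixing).
- Merged puncta are not split (no watershed), so island counts
  undercount dense fields and island-max pairs from merged islands mix
  puncta — visible as inflated residual scatter in the end-to-end fit.
- The permutation test treats images as exchangeable units; pixel-level
  spatial correlation within an image is not modeled beyond choosing
  permutation over parametric inference.
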