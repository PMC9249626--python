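# Methods

This note records the models, assumptions and numerical choices behind
`ishquant`, and what the synthetic validation does and does not demonstrate.

## Stain model and demultiplexing

Brightfield chromogenic images are modeled with the Beer–Lambert law:
transmitted intensity per channel is `I_c = I0_c · exp(-(C_H h_c + C_D d_c))`
where `h` and `d` are unit optical-density vectors of hematoxylin and DAB and
`C_H`, `C_D` are per-pixel stain concentrations. Demultiplexing computes
`OD_c = -ln(max(I_c, 1/512) / I0_c)` (the floor caps the dynamic range of an
8-bit image and avoids log of zero) and solves the 3×3 linear system per
pixel; the third matrix column is the normalized cross product of the two
stains, so residual absorbance orthogonal to both stains is absorbed rather
than leaked into them. Negative concentrations (quantization noise around
zero) are clipped.

Defaults and rationale:

- Stain vectors: the standard H-DAB pair, hematoxylin (0.650, 0.704, 0.286)
  and DAB (0.269, 0.568, 0.778), normalized. Real assays should calibrate
  vectors per staining protocol; they are a config field.
- White reference: per-channel 99th percentile of the pixels at or above the
  Otsu luminance threshold (the illuminated background), fallback 1.0. This
  makes the OD transform robust to scanners that do not reach full white.
- Marker "signal intensity": DAB concentration divided by a saturation
  constant (OD 2.0 ↦ 1.0), clipped to [0, 1]. On this scale 1 means a pixel
  fully saturated with chromogen; typical images sit around 0.001–0.01 at
  the cell level.
- Background suppression: Rényi entropy thresholding of the 256-bin signal
  histogram, order α = 0.5 by default (configurable); α → 1 reproduces the
  Shannon maximum-entropy (Kapur) threshold, which the implementation
  handles as an explicit limit. Ties resolve to the lowest threshold.

Fluorescent mode receives pre-separated marker and nuclear channels and
skips unmixing and restoration; the marker channel is min–max scaled with
fixed configured bounds so slides remain comparable.

## Nucleus restoration

Dense chromogen physically covers the counterstain, so after unmixing the
nuclear channel has voids wherever strong marker sits. The void mask is the
suprathreshold marker mask dilated by a 2 px Euclidean disk (covering the
dot halo). Voids are filled by discrete harmonic interpolation: the 5-point
Laplace equation is solved over void pixels with Dirichlet data from the
surrounding intact counterstain (mirror boundary at image edges), via a
sparse direct solve. Harmonic fill was chosen over patch-based texture
synthesis because it is deterministic, exactly reproduces constants and
affine ramps, and satisfies the maximum principle (filled values never leave
the range of the void's boundary values) — segmentation needs plausible
continuity, not texture. The interface is pluggable if a texture backend is
ever wanted.

## Segmentation

1. Robust rescaling: 1st percentile → 0, 99th → 1, clipped.
2. Adaptive Otsu: Gaussian pre-blur with σ = smoothing_scale / 2.35 — the
   "threshold smoothing scale" (default 1.3488) is interpreted as the FWHM
   of the blur, following the originating tool's convention — then per-tile
   Otsu thresholds on a 128 px grid, bilinearly interpolated into a
   threshold surface. Degenerate tiles inherit the global threshold; a tile
   larger than the image falls back to global Otsu.
3. Shape-based declumping: watershed on the Gaussian-smoothed (σ = 2 px)
   Euclidean distance transform, seeded by local maxima at least
   min_diameter/2 apart, constrained to the mask (so the union of labels is
   exactly the thresholded mask and components are never merged).
4. Size filter: equivalent circular diameter 2·√(area/π) in [25, 170] px,
   inclusive, applied after declumping; labels renumbered in raster order.

Otsu's criterion is implemented on an explicit 256-bin histogram and returns
a bin edge (lowest maximizer on plateaus). Because the histogram range
follows the data, the threshold is exactly shift-covariant. The adaptive
window (128 px) is a package default; it is not dictated by the upstream
parameterization.

## Cell classification

Four features per nucleus — area (px²), mean nuclear stain intensity (on
the rescaled channel, [0, 1]), eccentricity (fitted-ellipse convention from
second central moments), perimeter-to-area ratio (boundary-step perimeter
estimator) — feed a quadratic discriminant classifier with per-class full
covariances and uniform priors. Covariances are regularized by
ε·I (ε = 1e-6 · trace/4) when near-singular; fewer than 5 training cells per
class, or zero feature spread, is an error. Features are used unscaled: with
per-class full covariances the QDA decision is covariant to affine feature
rescaling, so standardization would not change assignments.

Spatial smoothing exploits the co-localization of cell types: per class, a
raster map assigns each labeled pixel its cell's *log* posterior
(background pixels carry the neutral value log(1/K)); maps are mean-filtered
with a uniform 100 px disk (about four cancer-cell radii) and read at each
cell's centroid, then renormalized. Two deliberate choices:

- Filtering happens on the natively normalized log posteriors, never on
  probabilities that were exponentiated and re-logged. Probabilities
  underflow at ~1e-300, which would cap all strong evidence at one
  magnitude and make neighborhood area decide every contested cell; keeping
  the true log range lets a cell with strong features retain its class.
- The smoothed value is read at the centroid rather than averaged over the
  cell — equivalent for convex nuclei and much cheaper.

Smoothing should be disabled (config switch) for tissue in which neighboring
cells are of thoroughly mixed types; the filter's premise is spatial
compartmentalization.

Segment expansion grows each nucleus into unlabeled space by a class radius
(cancer 20 px, immune 5 px, stromal 5 px — carcinoma cells carry much more
cytoplasm). A contested background pixel goes to the cell whose original
segment is nearest in Euclidean distance; residual exact ties go to the
lower label id. Original labeled pixels never change, and artifact classes
("small", "irregular", "large") are never expanded nor quantified.

## Quantification and QC

Nonspecific staining appears as saturated marker regions: seed pixels within
the 5 darkest of 256 display bins of saturation (signal ≥ 1 − 5/256 ≈ 0.9805
— note the display convention: dark = strong stain) are dilated by a 10 px
Euclidean disk and excluded. Per expanded cell, `Intensity_i` is the sum of
marker signal and `Area_i` the pixel count over the unmasked segment, so the
per-cell mean stays unbiased; fully masked cells are dropped with a logged
count. Spot-level positive-control QC applies a two-class Otsu split to the
spot-level weighted means of the housekeeping-control stain (computed over
cancer cells by default); spots below the threshold are excluded. Identical
values across spots pass everything with a warning.

## Expression statistics

The area-weighted mean and variance (`m`, `v`) weight out residual small
artifacts and emphasize large carcinoma cells whose average is reliably
estimated. The variability factor is the residual of an OLS fit of log₁₀ v
against log₁₀ m across samples (per gene, across patients; base 10). The fit
needs ≥ 3 samples with positive m and v and non-zero spread in log m;
samples with v = 0 are excluded from the fit and assigned the minimum
observed factor with a warning. Patient-level summaries pool all QC-passing
spots' cancer cells (area-weighted across spots); a per-spot-then-average
alternative is available by configuration.

The nested ANOVA decomposes expression variance over a fully nested
hierarchy (e.g. patient ⊃ phase ⊃ spot) using streaming group means: one
group-mean pass per nesting level yields the sequential sums of squares in
linear time, with each factor tested against the residual mean square.
Degenerate factors (a single level, or zero residual variance) are flagged
rather than silently reported.

## Survival analysis

Kaplan–Meier estimation and the k-group log-rank test are delegated to
`lifelines`; BH adjustment to `statsmodels`. Median splits put a patient
exactly at the median into the low group. The optimized three-way split
enumerates cut-fraction pairs on a 5% lattice over (20%, 80%) with t₁ < t₂,
in (t₁, t₂) order, keeping pairs that yield three non-empty groups and
truncating to 20 candidates; each candidate's log-rank p enters one BH
family (family size = candidates evaluated, controlling for the optimization
itself, not across genes), and the split with the smallest adjusted p wins
(ties → smaller first cut).

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, with
complete ground truth:

- Three morphologically distinct classes: cancer nuclei large and pale
  (equivalent radius 20–35 px, counterstain OD 0.30–0.50), immune small,
  round and dark (12.5–16 px, OD 0.8–1.2), stromal elongated (13–17 px,
  eccentricity ≥ 0.90). Immune/stromal radii were chosen so lymphocyte-scale
  nuclei (≈ 7 µm ≈ 28 px at 40x) survive the 25 px minimum-diameter filter.
- Compartmentalized placement: class territories occupy distinct grid sites
  with small jitter; per-class territory spread is sized from packing
  capacity (≈ 50% packing of the cells' footprints) so territories neither
  overflow nor overlap. This mirrors tumor nests, immune infiltrates and
  stromal bands — the co-localization the smoothing stage presumes. Cells
  failing clustered placement fall back to uniform positions.
- Dot process: per-cell dot counts are negative binomial with mean μ and
  dispersion k (variance μ + μ²/k; k = ∞ is Poisson) — the super-Poisson,
  mean-linked variance the variability factor presumes. Dots are Gaussian
  profiles (radius 3 px, σ = 1.5 px) with peak OD 1.7 (dense chromogen
  precipitate is nearly opaque), placed uniformly in the cell's cytoplasmic
  footprint (nucleus dilated by the class expansion radius, so expanded
  segments capture them by construction). Default means: cancer 5 dots/cell
  (the 1–10 probes/cell regime of amplified single-molecule assays; yields
  spot-level m ≈ 0.003–0.01), immune/stromal 1.
- Forward model: `I = white · exp(-(C_H_occ h + C_D d))` with
  `C_H_occ = C_H · exp(-4 · C_D)` — chromogen occludes the counterstain
  underneath, so the image remains an exact two-stain mixture while the
  nuclear channel genuinely loses morphology under dense signal (what
  restoration must repair). White level 0.96 (not 1.0) exercises background
  estimation. About 1 DN of Gaussian scanner noise is added before 8-bit
  quantization; without it the background histogram is a delta that no
  entropy threshold could split, which no real scanner produces.
- The `occluded()` preset raises dot density (cancer mean 100) to occlude
  ≈ 30% of nuclear area — the high-abundance stress case for restoration.
- Cohorts: per-patient log-normal mean dot count (median 8, ln-σ 0.5) and
  log-normal NB dispersion (median 2, ln-σ 1.0), several spots per patient
  (multiple ~1 mm cores per patient, as in TMA designs); exponential PFI/OS
  with log hazard optionally linked (0.7 per SD) to the injected mean or to
  −ln k (variability), censored at 120 months. Everything is deterministic
  given the seed (per-cell PRNG streams keyed by seed and cell index).

What the generator does **not** emulate: histology texture, chromatin
structure, out-of-focus blur, tiling seams, stain gradients across a slide,
overlapping/touching nuclei in 3D, or cell-type-dependent staining
protocols. Passing tests therefore demonstrate the pipeline's correctness on
images satisfying its own model assumptions (Beer–Lambert mixing, separable
morphology, compartmentalized classes) — not its accuracy on any particular
real cohort, which additionally depends on stain-vector calibration and
classifier training data.

## Validation problem sizes

The test suite and the acceptance script validate at these scales, chosen to
exercise each stage meaningfully while keeping a full run on one CPU within
minutes: stain round trips on 512×512 spots with 100 cells; segmentation
recovery on a 1280×1280, 200-cell spot with ≈ 30% nuclear occlusion (with
vs. without restoration); classification precision pooled over several
200-cell spots against ground truth; variability-factor recovery on 200
simulated samples (β = 1.6, residual σ = 0.3); nested-ANOVA equivalence to a
dense design-matrix oracle on 5×2×3×20 designs; log-rank type-I calibration
with 1000 null replicates at n = 60; and an end-to-end 90-patient cohort
(two 384×384 spots per patient, 12 cancer / 4 immune / 4 stromal cells per
spot) with hazard linked to injected variability, where the
variability-factor split detects the effect and the mean-expression split
does not.

## Known limitations

- Harmonic fill cannot reinvent texture; nuclei almost entirely covered by
  chromogen are reconstructed as smooth blobs and may still fail
  segmentation.
- Touching TMA cores are detected as one region (no dearraying grid model).
- The QDA classifier needs morphologically separable classes; heavily
  pleomorphic tissue may need a different classifier behind the same
  interface.
- Log-space disk-mean smoothing favors the locally dominant class at
  compartment boundaries; boundary cells of a minority class can be
  absorbed by a large adjacent majority compartment.
- The three-way split optimizer searches rank fractions, not raw thresholds;
  heavily tied expression values can make some candidate pairs coincide.
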