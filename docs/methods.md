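# Methods

This note records the models behind each stage of axotrace, the parameters
that matter, the choices made where published workflows leave the design
open, and what the synthetic phantoms do and do not establish about real
imaging data.

## Units and conventions

Pixel indices are 0-based; physical coordinates sit at pixel centers and are
carried in micrometres, with areas in µm² internally and reported in mm².
Masks are boolean arrays (nonzero = tissue) of the same shape as their image.
Every random stage consumes one `numpy.random.default_rng(seed)` stream per
call and no global state, so identical (spec, seed) input reproduces output
bit for bit.

## Soma detection in whole-mount retina

Published workflows for this assay rely on proprietary 2-D filter
subroutines with unreported thresholds; axotrace substitutes a standard
robust pipeline in fixed order, every stage a documented parameter
(`DetectionParams`):

1. **Background correction.** Non-tissue pixels are filled with the tissue
   median (so the estimate does not dip at the mask rim), then a large median
   filter (`background_scale_um`, default 120 µm ≈ 10 soma diameters)
   estimates slowly varying background, computed on a downsampled copy for
   speed — the background varies on scales far larger than a soma, so
   nothing the detector uses is lost.
2. **Smoothing.** Gaussian, σ = `smoothing_scale_um` (default 1 µm). The
   default is deliberately below the soma radius: at the generator's packing
   limit (center spacing 1.5 radii) heavier smoothing fills in the intensity
   valley between neighbors and merges them.
3. **Threshold.** Local background + `threshold_k` (default 3) robust SDs,
   with the robust SD = 1.4826·MAD of the corrected image over the mask.
   The threshold is floored at `threshold_floor_frac` (default 0.15) of the
   bright-tail amplitude (99.5th-percentile residual): on a noise-free image
   the MAD term vanishes and an unfloored threshold would collapse onto the
   background, segmenting each blob's entire smoothed tail. The floor is the
   degenerate-limit guard; on noisy images the MAD term governs.
4. **Labeling and separation.** 8-connected components; touching somata are
   split by watershed with markers taken as *connected regions of the local-
   maximum set* (maximum filter of width 2·`split_min_distance_um`+1).
   Connected-region markers matter: a bright streak artifact is an
   equal-valued ridge whose every point is a local maximum; treating the
   ridge as one marker keeps the streak in one piece so the shape filter can
   reject it, while two touching somata still provide two separated maxima.
5. **Filters.** Area window 15–300 µm² (brackets mouse RGC soma footprints),
   circularity 4π·area/perimeter² ≥ 0.4 (perimeter from scikit-image's
   boundary estimator, values clipped at 1), and centroid at least
   `edge_margin_um` (default 10 µm) from the mask boundary. Centroids are
   intensity-weighted, which is what makes sub-pixel agreement with seeded
   truth possible.

Determinism: the pipeline contains no randomness; identical image and
parameters give identical detections.

## Density and percent area intact (retina)

Density is the raw count over mask area. Sectorial dropout is measured by a
**tile-occupancy detector**: square tiles of side `tile_um` (default 100 µm),
a tile is devoid iff it contains no detected centroid, 8-connected devoid
tiles merge, and merged regions with tissue area ≥ `min_sector_mm2` (default
0.05 mm²) count as dropout. Region areas sum only the tissue pixels inside
their tiles, so rim tiles contribute their true sliver. A retina with no
detected cells is defined as 0 % intact (one region = the whole mask),
matching the treatment of near-complete loss as maximal deficit.

How FG-absent areas are delineated in published workflows (manual tracing
vs computation) is typically unstated; tiles make the statistic
deterministic and give a computable false-dropout rate: with expected density λ (cells/mm²) a full
tile is spuriously devoid with probability ≈ exp(−λ·tile²), negligible
(<10⁻⁴) above 1000 cells/mm² at the default tile. The price is
discretization at dropout borders: boundary tiles straddling the wedge edge
contain cells and count as intact, biasing percent-intact upward by roughly
half a tile width times the dropout perimeter. At a 1.8 mm retina radius this
is ≈ 2–3 percentage points for a 25 % wedge (the recovery experiments
measure it directly); for retinas only a few tiles across the statistic
loses resolution and small dropout regions fall below `min_sector_mm2` —
the tile defaults assume mm-scale whole-mounts.

## Collicular label density and intactness

Background per section is mean + `k`·sample SD (ddof = 1) of the reference
region; a pixel is signal iff **strictly** greater. "Brighter than
background" is not quantified in published implementations; k = 2 is a
conventional, configurable margin. Note its built-in consequence: ~2.3 % of
genuinely unlabeled pixels exceed a 2-SD margin under Gaussian noise, so
fully deficient regions read ≈ 2 %, not 0; per-bin recovery experiments use
k = 3 where that floor would dominate.

Profiles split the ROI's column extent into `n_bins` (default 100, ≈ 1 %
mediolateral resolution) contiguous near-equal spans by proportional
assignment; bins with no ROI pixel are NaN (flagged missing, never 0). The
`flip` flag mirrors the axis so left/right colliculi report medial→lateral
consistently. Map assembly resamples each profile linearly on the normalized
axis with endpoints at 0 and 1 — endpoint bins survive any down/up
resampling exactly — orders rows rostral→caudal, and scales to percent; the
blue→red rendering is a plotting utility with no bit-exactness contract.

Whole-structure intactness is the **pooled** labeled-pixel fraction over all
sections (each thresholded by its own reference), not a mean of binarized
bins: the "percent area fraction" reading of intactness is an area ratio and
pooling is parameter-free. The ROI-weighted mean of bin fractions equals the
pooled fraction exactly when no bin is empty (tested to 1e-12). Every-third-
section sampling is represented by the caller passing the sampled sections.

## Statistical battery

Projections (eye + contralateral SC) are treated as independent units, as
is standard for this assay — glaucomatous pathology affects the two eyes of
an animal differentially — and no animal-level clustering adjustment is
applied.

- **Factorial ANOVA**: two-way between-subjects, label × group, **Type II**
  sums of squares (group sizes are unequal; Type II is the standard
  main-effects-first choice and is checkable against nested-model residual-SS
  differences, which the tests do to 1e-10). Implemented over statsmodels
  OLS/`anova_lm`.
- **Protected Fisher's LSD**: pairwise t on the pooled residual MS with the
  ANOVA's residual df, no multiplicity correction; the `protected` flag
  records whether the omnibus effect reached α instead of suppressing
  output, keeping the battery auditable.
- **Paired t, Pearson r**: two-sided; degenerate inputs (zero-variance
  nonzero differences, constant vectors) raise typed errors rather than
  emitting infinite statistics.
- **Unity-line analysis**: per-case y − x, ties excluded, exact two-sided
  binomial sign test on below-vs-above counts (8 of 8 below gives
  p = 2·(1/2)⁸ = 0.0078125 exactly). With every point on the line there are
  no counts and the p-value is NaN.
- Percent measures are analyzed untransformed; a logit transform can be
  applied by the caller before the battery if desired.

**Calibration.** The type-I experiment draws null cohorts with *independent*
errors (cross-measure ρ = 0): the between-subjects F-test is only nominally
calibrated under independence, and with ρ > 0 (measures correlated within a
projection, as the default study cohort emulates) the label and interaction
tests are conservative by construction. The calibration check validates the
test statistic, not the treat-labels-as-independent modeling choice, which
this package reproduces as-is. Measured over 1000 replicates at
the study's group sizes (8, 6, 6, 9, 6) the interaction rejection rate is
0.05 ± 0.03; power against the study-patterned interaction (anterograde
collapse ≫ retrograde reduction in affected groups) exceeds 0.9 over 100
replicates.

## Phantom generators

**Retina.** Disc mask at 0.46·min(image size) with `radial_cuts` narrow
triangular notches (half-angle 1.5°, outer two-thirds of the radius)
emulating the relieving cuts of a flattened whole-mount — geometry only, no
tissue deformation. Somata are isotropic Gaussian blobs, σ = radius/2,
truncated at 3σ, placed by uniform rejection sampling (occupancy-grid
accelerated) inside mask∖wedges with hard minimum center spacing of 1.5
soma radii — merged somata would otherwise dominate small-phantom tests —
and at least `edge_clearance_um` (15 µm) from the rim, consistent with the
detector's edge exclusion. Noise is additive Gaussian clipped at 0, the
simplest model that exercises thresholding. Defaults: 1024² px at
1.5 µm/px, soma radius 6 µm (12 µm diameter, mid-range for mouse RGC somata;
its 3σ rendered footprint of ≈ 254 µm² lies inside the detector's size
window, a consistency the exact-recovery properties rely on), radius jitter
5 %, contrast 100 over background 20, noise SD 10 (10 % of contrast),
densities of order 10³ cells/mm². Dropout wedges are circular sectors;
ground truth records every placed centroid, the pixel-counted mask area and
intact fraction (within 1 point of the analytic sector formula).

**SC stacks.** Flat background plus a superficial signal band; per-section
deficit spans are fractional mediolateral intervals with no signal. Truth
stores the analytic per-bin intact fractions and the spans;
`quantized_bin_fractions` gives the pixel-accurate rendered truth for
bin-level comparisons (the two agree to within pixelization).

**Cohorts.** Per-group multivariate-normal draws of the four measures with
common pairwise correlation ρ (Cholesky of the equicorrelation matrix),
percents clipped to [0, 100]. `CohortSpec.default_study()` encodes the
*relative* deficit pattern reported for the DBA/2J model — ≈ 69 % anterograde vs ≈ 23 % retrograde
reduction at glaucoma onset, late joint collapse with ≈ 86 % structural loss
— around a 95 % baseline at group sizes of 6-9; absolute group
means are not available, so these are configuration, not ground truth.
Note that the pooled density-vs-percent correlation in such a cohort
(≈ 0.98) exceeds the within-group ρ = 0.8 because the group structure adds
shared variance across measures.

**What phantoms do not show.** No optics (PSF, vignetting), no montage
stitching seams, no vasculature or non-RGC labeling, no intensity gradation
of partially transported label, flat backgrounds, and geometric rather than
biological dropout. Passing recovery tests therefore demonstrates that the
measurement chain is correct and calibrated on data matching its
assumptions — not that the detector parameters are optimal for any given
microscope; on real montages the detection parameters are expected to need
tuning, which is why all of them are explicit configuration.

## Problem sizes and numerical choices

Recovery experiments run at sizes chosen to keep the full suite fast while
preserving the regime of interest: counting on 512–1024 px phantoms with
500 somata; density recovery at 1000–3000 cells/mm² over 10 seeds per
level; wedge recovery on 1536² px phantoms (1.8 mm radius) where tile
discretization is a small fraction of the wedge; calibration at the study's
exact group sizes. Tolerances: exact equality for pixel tallies and counts;
1e-10 against statistical oracles; 1e-12 for algebraic identities; recovery
bands of 5 % (density), ±5 points (dropout) and 2 points (SC bins) reflect
the discretization analyses above. The end-to-end pipeline writes CSV floats
with `%.17g` (round-trips every IEEE double), sorted-key JSON and no
timestamps, so reruns are byte-identical; timing information goes to the
logging stream only.
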