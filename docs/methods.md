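# Methods

This note documents the models, estimators, parameter choices and known
limitations of `octamorph`. It is the place where genuinely open design
decisions are recorded.

## Coordinate and calibration conventions

Pixels are addressed (col = x, row = y), 0-based, with the center of
pixel (row, col) at continuous coordinates (col + 0.5, row + 0.5). All
geometry — point-in-polygon tests, disc membership — is evaluated at
pixel centers, with centers exactly on a polygon edge counted inside
(closed-polygon semantics). The standard acquisition is a 4.5 mm field
sampled at 320 px, pixel pitch 0.0140625 mm/px; other calibrations are
supported through `EnFaceAngiogram.extent_mm`.

Intensities are min–max rescaled to [0, 1] on load (the scanner-side
export scaling is unknown, so a fixed convention is adopted); a flat
image maps to all-zero rather than dividing by zero. RGB input collapses
to luminance with Rec. 601 weights (0.299, 0.587, 0.114), stated here so
binarization is bit-reproducible.

## FAZ morphometry

Area is foreground-pixel count × pitch². The perimeter is measured on
the traced 8-connected (Moore) boundary chain of the single largest
component. Two weightings are available:

- **corner-corrected** (default): Vossepoel–Smeulders weights
  0.980·n_straight + 1.406·n_diagonal − 0.091·n_corners. This estimator
  is nearly unbiased for smooth contours: a rasterized ideal disc of
  radius 150 px measures circularity 1.002.
- **freeman**: raw pixel-to-pixel chain distances (1 / √2). Simple and
  exactly reproducible by hand, but it overestimates smooth contour
  length by ≈ 5.5% (the classic digitization bias), which would push an
  ideal disc's circularity down to ≈ 0.90. It is kept for comparison
  with software that reports raw chain lengths.

Small-object tolerance: for objects only a few pixels across the chain
estimate is noisy — circularity of small rasterized discs can exceed 1
by up to ≈ 0.05 (radius 10 px: ≈ 1.04), converging to 1 from above as
the radius grows. A single-pixel object falls back to perimeter =
4 × pitch, with a warning. Circularity is scale-invariant, so it is
never axial-length adjusted.

Axial-length adjustment uses the Littmann–Bennett scaling
q(AL) = 0.01306·(AL − 1.82); measured lengths scale by
q(AL)/q(AL_ref), areas by the square. The source text names no formula;
this choice is recorded as an explicit assumption, with the reference
axial length configurable (default 24.39 mm, a common instrument
assumption). Only FAZ area and perimeter are adjusted — not VD/VLD/FD —
matching the described workflow.

The 3-mm analysis disc is anchored at the unweighted FAZ-mask centroid;
the FAZ is excluded from the region, and the disc-minus-FAZ mask is the
denominator of every density metric (the alternative full-disc
denominator is available via the region object). A disc clipped by the
frame is used as-is with the clipped fraction reported as a warning flag.

## Vessel enhancement and binarization

The Frangi vesselness at scale σ uses γ = 2 normalized Hessian
eigenvalues (|λ₁| ≤ |λ₂|), blobness R_B = λ₁/λ₂ and structureness
S = √(λ₁² + λ₂²):

    V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),  V = 0 where sign(λ₂) is
    wrong for the polarity (bright vessels ⇒ λ₂ < 0),

maximized over scales σ ∈ {1, 1.5, 2, 2.5} px (capillaries are ~1–3 px
at this sampling). Defaults β = 1.0 and c = 0.5 × the 99th percentile of
S (per scale) were calibrated against phantom ground truth: the textbook
β = 0.5 and c tied to the single maximum S suppress vessel crossings
and junctions enough to bias vessel density low by ~8 percentage points.
All parameters are config-exposed.

The display-oriented "inversion" step (1 − V) is provided as an explicit
optional stage; computationally the package binarizes the vesselness map
directly with foreground = high vesselness, which is the mirror-image
decision and is documented here.

Phansalkar thresholding: per pixel, with m and s the mean and standard
deviation over a square window of radius R (edge-replicated padding),

    T = m · (1 + p·e^(−q·m) + k·(s/r − 1)),  foreground iff value > T.

R = 7 px, k = 0.25, r = 0.5, p = 2 keep the published values; q defaults
to 20 (published: 10), again calibrated on phantom ground truth —
vesselness maps are globally much darker than the stained-cytology
images the published constants target, and q = 10 inflates T in dim
regions enough to erode ≈ 1 px from each vessel flank. Window statistics
always use all window pixels (including FAZ-masked ones) to avoid
boundary bias; the region restriction applies to the output only.
With these defaults the segmentation achieves Dice 0.77–0.85 against
ground truth and recovers true vessel density to within 0.035 across
phantom seeds.

## Perfusion metrics

VD = vessel pixels ∩ effective region / effective region area. The
skeleton is produced by topology-preserving thinning (Lee's method plus
a simple-point prune of residual 2 × 2 blocks); at raster 4-way
crossings a 2 × 2 junction block is irreducible — deleting any of its
pixels would disconnect an arm — so strict 1-px width holds everywhere
except at those crossings, and connectivity is never sacrificed. VLD
counts
skeleton pixels per region area (the common OCTA convention for skeleton
density), with a √2-weighted chain-length option available but off by
default. The skeleton for VLD and FD is computed after restricting the
vessel map to the effective region.

Box-counting FD tiles the plane with boxes of side ε ∈ {2, 4, 8, …,
min(frame)/4}, anchored at the foreground bounding-box origin (fixed
anchor, no offset averaging), and fits log N(ε) against log ε by least
squares; R² < 0.95 triggers a warning and at least 4 sizes are required.
Note the estimator's finite-size bias: for a filled disc the boundary
contributes an O(ε/r) excess count, so the 2-D reference value is only
recovered (within 0.05) when box sizes stay small relative to the
object; the reference tests use a radius-230 disc with ε ≤ 16.

## AO wall morphometry

The wall-to-lumen ratio uses the two-wall convention
WLR = (TVD − LD)/LD = 2·WT/LD. The single-wall reading WT/LD is
inconsistent with published group-level values (control means TVD
100.341 µm, LD 81.085 µm give 0.237 under the two-wall convention
versus 0.119 single-wall); the discrepancy and its resolution are
documented here. Metrics are derived per ROI and then averaged (mean of
per-ROI ratios, not ratio of mean diameters). Axial-length adjustment of
AO metrics is optional (off by default, since whether exported values
are already corrected is instrument-dependent); WLR is unaffected either
way.

## Cohort statistics

Shapiro–Wilk is applied per group at α = 0.05; ANOVA (+ Tukey–Kramer)
is used only when every group passes, otherwise Kruskal–Wallis
(+ Dunn). Dunn's z uses tie-corrected pooled rank variance; adjusted
p-values are Bonferroni over the k(k−1)/2 pairs, capped at 1 (matching
common clinical software), with Holm available. All tests are two-sided;
no variance-homogeneity gate and no correction across parameters is
applied. Spearman p uses the t approximation (adequate at the n ≈ 40–70
scale this package targets). A zero-variance group routes to the rank
branch with a warning, since Shapiro–Wilk is undefined there.

## Synthetic generators

**Phantom.** The avascular zone is a radial-Fourier-perturbed circle
(harmonics 3–8, amplitude = irregularity knob, default mean radius
0.27 mm ⇒ area ≈ 0.23 mm², a healthy-eye scale). Capillaries grow as a
space-filling branching random walk with momentum: walkers enter from
the frame edges, branch with probability 0.08/step, terminate at the
avascular zone, and their centerlines are dilated to a mean caliber of
2.5 px (~35 µm). Growth stops when disc-minus-FAZ coverage reaches the
target density (default 0.35), giving truth densities within ±0.01 of
target. Intensity = Gaussian-blurred mask (σ = 0.8 px) + additive
Gaussian noise (σ = 0.05), clipped to [0, 1]; truth masks are pre-noise.
The degradation operator deletes a seeded fraction of branches
(capillary dropout) and optionally notches the avascular-zone boundary
with higher-frequency harmonics (9–14, so the perturbation cannot
phase-cancel the base shape), emulating severity-related irregularity.

The phantom reproduces the geometry and first-order statistics of
en-face capillary frames, not OCTA speckle, projection artifacts, flow
decorrelation or real capillary anatomy — so passing tests demonstrate
correct measurement of known geometry, not clinical-grade segmentation
of real angiograms.

**Cohort.** Per-eye metrics are drawn from truncated Gaussians at the
published per-group means/SDs, independently per metric (cross-metric
covariance is unknowable from group-level summaries and is not
modeled), except the AO block: LD and WLR are drawn and TVD, WT, WCSA
derived from them, which keeps TVD > LD > 0 and the wall identities
exact for every record while implying TVD/WT group means within ~4% of
the published ones. Truncation respects each metric's domain (densities
in [0, 100]%, FD in [1, 2], decimal BCVA in (0, 1]); bounds that exclude
mean ± 4 SD are rejected. For strongly right-censored metrics (BCVA in
the upper groups) truncation shifts the realized mean below the nominal
one; group contrasts remain qualitatively intact.

## Problem sizes used in the test suite

Deterministic references: radius-150 and radius-230 discs, depth-7
Sierpinski raster, 64² threshold-oracle images (50 seeds). Stochastic
suites: 8–20 phantoms for segmentation/skeleton properties, 100 seeded
trials for degradation monotonicity, 24 pipeline runs (4 target
densities × 6 seeds) for the density-recovery sweep, 50 seeded cohorts
for the group-contrast recovery check, and 400 seeded cohorts for the
control-group FD calibration check. These sizes give comfortable
margins on every asserted proportion while keeping the default test run
short.

## Known limitations

- Absolute VD/VLD/FD depend on enhancement and threshold parameters;
  cross-study comparison requires identical configurations.
- The perimeter estimator's small-object bias (~+4% circularity at
  radius 10 px) means FAZ circularities of very small zones are
  optimistic; values are still comparable within a fixed pipeline.
- Dunn's Bonferroni adjustment is conservative for 6 pairs.
- One eye per record: no patient-level clustering or mixed models.
- The skeleton-density VLD of the phantoms (~10%) is lower than
  published clinical values (~29%), reflecting the phantom's coarser
  inter-capillary spacing rather than an estimator property.
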