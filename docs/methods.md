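# Methods

## Measurement model

A polarization-sensitive OCT volume is a pair of complex fields H(z, x, y)
and V(z, x, y) on a raster of `n_x` A-lines × `n_y` B-scans (defaults
512 × 256 over a nominal 6.0 × 6.0 mm macular field) with axial pixel
size Δz ≈ 4.33 μm. Depth `z` increases into the tissue; en-face arrays
are indexed (x, y) with superior toward y = 0 and the nasal side set per
eye by the `nasal_side` flag (`image_left`/`image_right`) — anatomy is
never inferred from laterality alone, because scan orientation is a
device convention.

### DOPU with noise-bias correction

Per voxel, Stokes parameters are I = |H|²+|V|², Q = |H|²−|V|²,
U = 2 Re(H V*), V = −2 Im(H V*). The sign of V is a convention; DOPU is
invariant under any consistent choice, so one is fixed and documented.
Stokes elements are averaged (unweighted) over a kernel of 3 axial × 3
lateral pixels **within** a B-scan — ≈13 μm × 35 μm at the default pitch
— and DOPU is the norm of the averaged (Q, U, V) divided by averaged I.

Additive detection noise with per-channel powers n_H, n_V (estimated as
mean |H|², |V|² over a signal-free region, by default the top 30 vitreous
rows; at least 100 voxels required) biases I by +(n_H+n_V) and Q by
+(n_H−n_V), while U and V are unbiased for circular complex noise. The
correction subtracts these biases *before* kernel averaging. Numerical
choices:

* **Edge policy** — kernels are truncated at volume borders: the mean is
  taken over the voxels actually present. No padding values are invented.
* **Clamping** — the corrected ratio can exceed 1 by noise fluctuation;
  valid values are clamped to [0, 1].
* **Validity** — voxels whose kernel-mean corrected intensity is at or
  below `eps_valid × (n_H+n_V)` (default `eps_valid = 2`) are flagged
  invalid and excluded from every downstream count. With a zero noise
  estimate the floor is 0, so signal-free voxels are invalid.
* Kernel averages are plain means of per-voxel Stokes elements, not
  intensity-normalized per voxel; that is the formulation the bias
  subtraction is exact for.

A voxel is **low-DOPU** iff it is valid and DOPU < 0.8 — strictly: a
voxel at exactly 0.8 is not low. The 0.8 threshold is the protocol
constant for melanin-containing tissue.

### Choroid segmentation

Two routes. The *import path* reads per-A-line inner/outer surfaces from
CSV (`x_px, y_px, z_inner_px, z_outer_px`, 0-based), validates ordering
(crossing surfaces are rejected naming the offending A-line) and flags
missing A-lines unsegmented. The *bundled heuristic* works on the
log-scaled intensity volume: per A-line the brightest thin band
(RPE/Bruch's complex) is located on a 3 × 7 px smoothed image, the inner
boundary is placed `inner_offset_px = 2` below it, and the outer boundary
is the deepest depth where the smoothed intensity stays within
`outer_drop_db = 2` dB of the B-scan's choroid median (computed over a
probe window below the inner boundary, ignoring vessel-dark pixels) for
`run_px = 8` consecutive pixels. Both surfaces are median-smoothed
(5 × 5) laterally. A-lines whose peak is within 8 dB of the volume noise
floor are flagged; more than 20% flagged aborts the run. On clean
phantoms the heuristic recovers both surfaces to ≈1 px mean absolute
error; all quantitative recovery experiments nevertheless use the import
path with ground-truth boundaries so that segmentation error and metric
error stay separable.

### Vessel/stroma binarization

Within the choroid of each B-scan, intensities (dB, lightly
masked-smoothed with a 3 × 3 mean) are quantized to 64 bins and every
pixel is thresholded at the Otsu cut of its 31 × 31 window's histogram,
restricted to choroid pixels (windowed histograms via per-bin uniform
filters; the Otsu core is an exact vectorized between-class-variance
maximization with ties broken toward the lower threshold). Bright pixels
are interstitial stroma, dark are vessel lumina. A binary median filter
(radius 2) removes salt-and-pepper misclassification. Pixels whose window
holds fewer than two occupied bins inherit the nearest valid threshold.

Plain Otsu *always* splits a window's histogram, even when the window
contains one tissue class — for a unimodal (approximately Gaussian)
window the between-class/total variance ratio at the Otsu cut is ≈ 0.64
and about half the window is labelled dark. A **bimodality guard**
therefore compares that ratio against `min_separation = 0.7`: weakly
separated windows are assigned wholly to stroma, or wholly to vessel if
the window mean lies below a dark floor (the pipeline derives it from the
noise estimate, +3 dB). Setting `min_separation = 0` restores plain local
Otsu. Window size, median radius and the guard are configuration, since
the underlying protocol publishes neither.

### Maps, guard band, sectors

Per A-line: choroidal thickness = (z_out − z_in)·Δz; MeCh thickness =
(count of low-DOPU ∧ stroma ∧ choroid voxels)·Δz; occupancy = that count
over the stroma count (A-lines with zero stroma are invalid). A kernel
centred on the **first** choroidal row straddles the RPE band above it,
which is itself strongly depolarizing, so its low-DOPU reading does not
reflect stromal melanin; rows within the kernel's axial half-width of the
inner boundary (default 1 row ≈ 4.3 μm) are excluded from both counts
(`inner_guard_px`). Region occupancy is aggregate-of-counts — total
qualifying voxels over total stroma voxels — not a mean of per-A-line
ratios (a flag switches); invalid A-lines are excluded from numerator and
denominator alike.

Sector masks: discs of 2 and 5 mm diameter centred on the fovea (a pixel
belongs to a disc when its centre is within the radius), the outer ring
split by the ±45° diagonals into superior/inferior/nasal/temporal; pixels
exactly on a diagonal go to the clockwise-following quadrant
(deterministic). The circle radii are applied on the magnification-
calibrated grid: pitch is scaled by q(AL)/q(AL_ref) with
q(AL) = 0.01306 (AL − 1.82) and AL_ref = 24.2 mm (configurable); axial
lengths outside [15, 35] mm are rejected. The measurement grid is
rescaled, not the image.

### Statistics

Simple regressions are Pearson (a Spearman flag exists, since rank
correlation is an equally defensible reading of "correlation
coefficient"). Stepwise multiple regression standardizes all variables,
enters the candidate with the smallest partial-F p if p < 0.05, removes
included predictors with p > 0.10, and at the final step reports
standardized β with 95% CI for retained predictors and "if entered"
statistics for excluded ones (the output structure SPSS prints); an
iteration cap guards against entry/removal cycling, and near-collinear
predictors are rejected naming the worst pair. The Wilcoxon signed-rank
test drops zero differences, and for n ≤ 25 enumerates the exact null of
the positive-rank sum by a dynamic program over doubled midranks (ties
handled exactly); beyond that a normal approximation with tie and
continuity corrections is used; two-sided p = min(1, 2·min(P≤, P≥)). The
Friedman statistic uses midranks with the standard tie correction (fully
tied data gives χ² = 0, p = 1); post hocs are Dunn-type z-tests on mean
ranks with Bonferroni multiplication over all pairs, clamped at 1. CV is
the per-eye sample SD over the mean of ≥ 2 positive repeats, summarized
as cohort mean ± SD.

## The phantom

The generator emulates the posterior eye as flat-to-smooth layer
surfaces per A-line: vitreous (signal-free), neural retina (reflectivity
0.3, with a Gaussian foveal pit of the inner surface, 60 μm deep,
σ = 400 μm), a 15-μm RPE band (reflectivity 1.0, depolarizing), the
choroid (inner boundary at RPE bottom; thickness 220 μm plus an optional
60 μm Gaussian central thickening, σ = 900 μm, mimicking the thicker
subfoveal choroid), and sclera (reflectivity 0.1). Default noise power
0.0125 per channel gives per-channel SNR 20 (13 dB) in the stroma —
a realistic posterior-segment level.

* **Speckle** — every reflective voxel carries a circular complex
  Gaussian amplitude with layer-specific mean power (fully developed
  speckle; exponential intensity). Polarization-preserving voxels share
  one pure state (default 45° linear so both channels carry signal);
  depolarizing voxels (RPE, melanin) get an independent per-voxel state
  drawn Haar-uniformly, i.e. uniform on the Poincaré sphere.
* **Vessels** — straight tubes along the fast axis at random (y, depth)
  with radii 40–80 μm, following the local choroid contour, kept at
  least 40 μm clear of both boundaries (so the boundary rows are always
  tissue); lumina are signal-free.
* **Melanin** — a Gaussian random field is smoothed to a correlation
  length of `melanin_cluster_um = 300` μm (per-axis smoothing σ floored
  at 1.5 px so clusters remain resolvable on reduced grids — a melanin
  region narrower than a voxel would be a sub-voxel mixture a binary
  label cannot represent), rank-transformed to uniform within the
  stroma, and thresholded at ρ, making the stroma-conditional melanin
  fraction equal ρ to within 1/N while melanin aggregates into
  lobule-scale clumps. `melanin_cluster_um = 0` gives voxel-independent
  Bernoulli placement — with a 3 × 3 averaging kernel that regime is
  *not* recoverable by thresholded DOPU (one kernel needs only ~2/9
  depolarizing voxels to read low), which is the physical reason the
  clustered default exists. ρ may vary per A-line (`rho_map`) to build
  regional gradients.

Everything is deterministic given the parameter set and seed. Ground truth
records the class volume, boundary surfaces, stroma and melanin masks,
the three per-A-line truth maps and a truth sector table.

**What the phantom does not emulate** — and what passing tests therefore
do not certify about real data: depth-dependent signal attenuation and
shadowing under vessels; the axial point-spread function and speckle
correlation; motion and blink artifacts; incident-polarization-state
variability and corneal/retinal birefringence (a known source of
between-measurement DOPU variation on fiber-based systems); curved or
pathological anatomy (staphyloma, detachments, exudate — which can
itself lower DOPU); multi-scan coherent compositing (the input is a
single composite volume). Conclusions about real eyes still require
instrument-level validation.

## Problem sizes and runtime choices

Unit and acceptance tests run on reduced rasters that keep the full
6 × 6 mm field (so the 5-mm sector grid always fits): 128 × 64 and
256 × 128 A-lines/B-scans with 160 axial pixels, sizes at which the full
pipeline runs in seconds to ~half a minute per volume. Recovery
tolerances (occupancy within ±0.05 of ρ, MeCh within ±10% of truth) were
set by the DOPU kernel's intrinsic blur at cluster boundaries, and the
256 × 128 grid meets them with margin (measured errors ≤ +0.014
occupancy, ≤ 5% MeCh across ρ = 0.12–0.73). The synthetic cohort uses
n = 105 eyes, matching the cohort design the statistics are meant for.

## Known limitations

* The bundled choroid heuristic is a stand-in for proprietary clinical
  segmenters; it is validated only on phantoms. Use the import path for
  externally segmented data.
* MeCh thickness is a count of low-DOPU pixels, not a physical melanin
  thickness: kernel size, melanin packing and the 0.8 threshold all
  scale it. Comparisons are meaningful within one protocol only.
* The occupancy estimator inherits a small positive bias from kernel
  dilation at melanin-cluster boundaries; the inner guard band removes
  the RPE-adjacency component but not this one.
* Local Otsu binarization assumes vessels dark / stroma bright; inverted
  contrast (e.g. projection artifacts) would silently flip classes.
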