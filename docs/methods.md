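# Methods

This note records the models, parameter choices and numerical decisions
behind `foveamap`, and what the synthetic test surface does and does not
establish about real data.

## Synthetic mosaic generator

The generator emulates the statistical structure of confocal AOSLO foveal
montages: quasi-hexagonal cone packing with a steep central density peak,
per-cone reflectivity variation, diffraction-limited blur, detector noise.

**Density profile.** ρ(r) = base + (peak − base)·exp(−r/falloff), with r the
eccentricity from the field center. Defaults — peak 15,000 cones/deg², base
6,000, falloff 0.5 deg, 600 px/deg — are of the physiological order for the
human foveola but are *synthetic choices*, not fitted to any dataset; no
quantitative noise or reflectivity statistics of real montages were
available to fit.

**Point process.** A hexagonal lattice of spacing s has density
ρ = 2/(√3·s²), so the local target spacing is s(ρ) = √(2/(√3·ρ)). Darts are
thrown with acceptance probability ρ/ρ_max and an exclusion distance of
0.7·s(ρ) until the target count N = ∫ρ dA is reached, then 30 Lloyd
(density-weighted discrete centroidal) sweeps hexagonalize the
configuration. Throwing darts at the full spacing s(ρ) cannot reach the
target density — sequential exclusion saturates near 55% coverage (the
random-sequential-adsorption jamming limit) — so the *count* carries the
density exactly and relaxation restores the spacing. On flat profiles the
realized density is exact up to rounding; interior Voronoi neighbor counts
average ≈ 6. For peaked profiles the relaxation is weighted by ρ; 30 sweeps
are few enough that points do not migrate globally, which keeps the realized
gradient close to ρ (an unweighted CVT would flatten it toward ρ^1/2).
A spec whose peak density implies s < 1 px is rejected as unresolvable.

**Rendering.** Cones are splatted bilinearly as sub-pixel impulses with
lognormal amplitudes (unit mean, CV = `reflectivity_cv`, default 0.3); a
`dropout_fraction` subset (default 3%) is scaled to 5% amplitude to emulate
wave-guiding reflectivity loss; the field is blurred with a Gaussian PSF
(FWHM default 3 px ≈ 0.3 arcmin, a diffraction-limited scale at 600 px/deg;
an Airy kernel is a non-goal), Gaussian noise (SD 3% of peak) is added, and
the image is min-max normalized to [0, 1]. Not emulated: rods, vessel
shadows, montage seams, eye-motion distortion, interference artifacts at the
foveal center. Passing tests on this surface therefore demonstrate the
*pipeline's* correctness and trainability, not performance on real montages.

## Preprocessing

Masks erode with the 4-connected (von Neumann) structuring element; presets:
64 iterations before training-crop extraction (border artifacts must not
enter the loss), 2 at inference (keep content). Distance labels are the
Euclidean distance from each pixel center to the nearest (sub-pixel) cone
center, clipped at 8 px: an uncapped target lets cone-free borders dominate
the regression; the cap is configurable. Training crops are sampled
uniformly inside the valid-mask bounding box. Inference tiles the image with
stride = size − overlap (default overlap 32), shifts the last row/column
inward, and averages overlapping predictions when stitching; tile→stitch is
the identity on covered pixels.

## Distance-regression U-Net

Architecture: encoder of depth+1 = 4 resolution levels, each a block of
k = 2 sub-blocks (3×3 zero-padded conv → batch norm → ReLU), channels
doubling per level from `base_filters`; 2×2 max pooling between levels;
dropout p = 0.2 at the lowest resolution; decoder with 4×4/stride-2/pad-1
transposed convolutions, skip concatenation, k = 2 sub-blocks halving
channels; final 1×1 conv to one channel. Output size equals input size for
any input divisible by 2³.

The stack is implemented directly in numpy (float32, NHWC, im2col + BLAS
matmul convolutions, analytic backward passes verified against float64
finite differences). Training uses MSE loss (MAE available), Adam at 1e-3,
batch 8, random flips and 90° rotations. Loss, optimizer and filter counts
are design choices of this package. Runs are deterministic given the seed on
a fixed BLAS configuration; checkpoints (single `.npz` with weights, batch
norm statistics and config) reload to bit-identical predictions.

**Problem sizes.** The scaled study conditions used by the test suite and
`scripts/acceptance.py` are: 30 training + 5 held-out mosaics of 160×160 px,
~210 crops of 64×64, `base_filters` 8, 25 epochs, 80:20 train/val split.
These sizes were chosen so a full from-scratch run completes in minutes on
one CPU core while still reaching mean F1 ≈ 0.99 on held-out mosaics; the
architecture default remains `base_filters` 32 at 256×256.

## Detection and RAPS

The network regresses a distance transform, so cone centers are *minima* of
the prediction (equivalently maxima of its negation). Candidates are local
minima within a `min_separation_px` (default 3 px) disk, kept where
D < `dist_threshold_px` (default 3 px — below half the smallest plausible
cone spacing at 600 px/deg); plateaus collapse to their centroid; single
minima are refined by per-axis parabola fits clamped to ±0.5 px. Raising the
threshold can only add detections.

RAPS minimizes `E = (1−α)·E_ext + (α/2)·E_int` by projected gradient descent
with backtracking (a step is accepted only if E does not increase; the step
halves on rejection), never changing the particle count. The influence term
is I(p, n) = (‖p−n‖ − d₀)², which vanishes on a perfect lattice at the
preferred spacing; with `preferred_spacing_px="auto"`, d₀ is the median
incident Delaunay edge length at each particle, tracking the local density
gradient. Neighbors are Delaunay adjacency extracted via the Voronoi dual,
with edges longer than 1.5× the median edge pruned — border slivers and the
degenerate diagonals of cocircular configurations would otherwise distort
both d₀ and the energy. α defaults to 0.3; the functional form of I and the
optimizer are this package's choices.

RAPS is **off by default**. On the synthetic surface it recovers jittered
lattices (mean localization error strictly decreases) but *worsens* the
Chamfer distance of already-accurate network detections — when particles
start at distance-map minima the external gradient vanishes and the
regularity term dominates, drifting sub-pixel positions. This mirrors the
original finding that its gains were marginal.

## Evaluation protocol

Matching threshold d = 0.35 × the minimal pairwise ground-truth distance
across all evaluated images (degenerating to one image's minimum when only
one is given). Predictions outside the convex hull of the ground truth are
excluded first. Matching is globally greedy over candidate pairs sorted by
ascending distance (ties broken by index), which realizes the nearest-wins
duplicate rule deterministically and provably equals the exhaustive optimum
whenever cone spacing exceeds 2d — guaranteed by the threshold definition;
the test suite verifies equality against a Hungarian-assignment oracle on
hundreds of random instances. Chamfer distance is implemented one-directional
(ground truth → predictions), exactly as defined. Correction time is
(FP + FN) × 3 s, reported in minutes.

## Topography

**Voronoi-k density** (default k = 150): at each probe of a regular grid
(default step 10 px), density = (number of *bounded* cells among the k
nearest cones) / (their combined area). Dividing the bounded count by the
bounded area keeps the estimator defined near borders; probes with > 20%
unbounded cells are invalid. **ICD density**: per cone, ICD = mean distance
to Voronoi-edge-sharing neighbors, density = 2/(√3·ICD²); off-cone probes
take the nearest source cone's value. The hexagonal assumption biases
non-hexagonal packing upward (a square lattice reads 2/√3 ≈ 1.155× its true
density) — a documented property, not corrected. **Yellott's ring**: each
Hann-apodized window (default 128 px) is Fourier transformed; the radially
averaged log power spectrum (3-bin smoothed) is searched beyond the DC lobe
for its peak above a running-median trend. A window is valid only if the
peak stands ≥ 0.35 log₁₀ units above the trend *and* the profile rises
≥ 0.35 log₁₀ units from its dip before the peak — a ring is an annular local
maximum, which featureless or monotone spectra (white or blurred noise) do
not produce. The ring frequency converts to density via ρ = (√3/2)·f*²
(hexagonal row spacing r = (√3/2)·s, f* = 1/r), validated against rendered
lattices rather than asserted. Windows spanning strong density gradients may
be rejected; that is intended. No correction is applied for the known
systematic underestimation of spectral density estimates.

**Landmarks.** PCD is the maximum of the valid map. The CDC is the
density-weighted centroid of the probes with values ≥ 80% of the peak
("top 20%" read as a fraction of the peak value, not a pixel-count
percentile; the component containing the peak is used if the region is
disconnected). **Group statistics** resample each map with its CDC at the
grid center (bilinear; the alignment rule is this package's choice) and
compute pointwise mean and SD (ddof = 1) where ≥ 2 eyes contribute;
z = (x − μ)/σ, with σ = 0 pixels valid (z = 0) only where x = μ.
**Profiles** bin valid probes into annuli (radial average) or sample the
probe line through the center with signed eccentricity (meridians);
eccentricity is measured from the CDC. Densities are cones/deg² given a
px/deg scale and convert to cones/mm² by (1000/RMF)² with the retinal
magnification factor in µm/deg.

## Degenerate inputs and numerical choices

Empty cone sets, all-constant distance maps, collinear ground truth (convex
hull undefined), empty eroded masks and sub-minimum-size images are either
rejected with specific errors or warned, as contracts require. Voronoi/
Delaunay degeneracies from perfectly regular inputs are handled by the
Voronoi-dual adjacency plus long-edge pruning (detection) and by qhull's
cocircular merging (ICD). Quadratic sub-pixel refinement falls back to the
integer position when the 3×3 neighborhood is not convex. All randomness
flows from explicit integer seeds through numpy `SeedSequence` streams.

## Known limitations

Real-montage performance is not established here: the simulator omits the
image phenomena (interference artifacts, rods, seams) that the original
dataset-trained network had to overcome, and the scaled training runs use a
reduced-capacity configuration. The Yellott estimator reports no value in
gradient-dominated or artifact-heavy windows rather than guessing. RAPS is
exposed for experimentation but disabled by default, as shipped.
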