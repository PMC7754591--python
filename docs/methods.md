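# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic phantom does and does
not emulate, and the numerical decisions taken where the design was open.

## Image model and conventions

Volumes are 3D scalar grids with anisotropic spacing, by default
0.5 × 0.5 × 3.0 mm³ (in-plane × slice), stored `(z, y, x)` with spacing
and origin in `(x, y, z)` mm. Masks share the geometry of their reference
volume; the analysis VOI is an inclusive 0-based slice range `[z_start,
z_end]`, matching how an operator picks the two delimiting slices of the
third metacarpal. Fat-fraction volumes live on the per-mille scale
[0, 1000]. NIfTI is the only on-disk format; masks are uint8 0/1 and any
nonzero value reads as true.

## Bias-field correction

MR coil inhomogeneity appears as a smooth multiplicative field. The step
is pluggable with three implementations behind one interface:

* `polyfit` (default): a trivariate polynomial (order 2) is fitted by
  least squares to the log-intensities of tissue voxels and divided out.
  Darker tissue classes (muscle, bone) would drag the polynomial into
  anatomy, so the fit domain is restricted to the dominant intensity
  class: starting from the 70th intensity percentile, the class center
  and scale are re-estimated iteratively (scale from the upper,
  uncontaminated side of the center; window center ± 2.5 scale). On an
  already-uniform volume the estimated field is flat to well under 1 %;
  when a strong bias smears the histogram the window widens and the fit
  gracefully reverts to all tissue voxels, trading some anatomy leakage
  for bias removal.
* `n4`: a thin wrapper around SimpleITK's N4 correction with Otsu
  foreground masking and optional shrinking.
* `none`: identity, for data that is already corrected.

The log-field is normalized to zero mean over the fitted voxels so
correction preserves the overall intensity scale.

## Intensity normalization

Grey values are mapped affinely so the cortical-bone histogram peak sits
at 0 and the muscle peak at 100. The two peaks are found inside the hand
mask only (air would otherwise dominate the histogram) by a watershed-like
thresholding of the smoothed 256-bin histogram: a count level rises from
zero; bins above the level form basins; the first level at which exactly
two basins remain yields the peaks (basin maxima, lower = cortical bone).
Two guards make this robust: basins whose maximum is below 1 % of the
global maximum never count (noise-floor clutter in sparse tails), and a
surviving pair is only accepted if both maxima exceed 1.5× the separating
level — near-top noise splits have peak/valley ratios close to 1 and are
rejected, so a unimodal histogram raises an error instead of returning an
arbitrary pair (the caller may then supply peaks manually). On histograms
with tens of thousands of samples, spurious split ratios stay below about
1.1, well clear of the 1.5 threshold.

## Hand CSA segmentation

Threshold 70 on the bias-corrected volume (the threshold refers to the
corrected, not the normalized scale: background ≈ 10, hand ≈ 500),
morphological opening with an in-plane disk of radius 1 (no extent along
z — opening across 3 mm slices would destroy thin structures), then the
largest 26-connected component. 26-connectivity is used for all component
labeling; it is robust under the 6:1 spacing anisotropy.

## Feature bank (21 channels, fixed order)

* Neighborhood mean and SD over city-block (diamond) neighborhoods:
  radii 1, 2, 3 in-plane only; radii 4, 5, 6 with the same in-plane
  diamond repeated on the two adjacent slices (the "3D" variant). The
  adjacent-slice extent is interpreted as the full in-plane diamond on
  each of the three slices.
* Sobel gradient magnitude, 2D per slice (z-gradients are incomparable at
  3 mm slices): √(gx² + gy²) with the standard 3×3 kernels.
* Extended local binary patterns, per slice, with n samples equidistant
  on circles of radius r and r/2, bilinearly interpolated, ordered
  counterclockwise from α = 0. Codes: CI (voxel vs slice mean, restricted
  to the hand mask when given), NI (voxel vs mean of the outer-circle
  samples), RD (bit k set iff the inner sample is brighter than the outer
  sample at angle α_k), AD (bit k set iff the outer sample at α_k is
  brighter than at α_{k+1}, wrapping). Bit k has weight 2^k; ties give 0.
  Comparisons use a 1e-6 absolute tolerance so interpolation round-off on
  exactly tied samples (e.g. clamped border samples) cannot mint bits.
  RD/AD are exactly invariant under any strictly increasing intensity map
  when samples are lattice-aligned and under affine maps in general;
  CI/NI reference a mean and are affine-invariant only.
* Gabor bank: real (cosine, zero-phase) kernels, σ and λ in mm converted
  through the in-plane spacing, square kernel (even sizes rounded up to
  odd), orientations exactly 0°, 45°, 90°, 135°, applied per slice.

Border policy everywhere is nearest-edge replication; first/last slices
replicate themselves for the 3D statistics. The channel order is frozen in
`CHANNEL_CATALOG` and models refuse feature tensors whose catalog differs.

## Classifier and parameter search

A random forest with per-node feature subsampling fixed at √21 ≈ 4.
Tunable: number of trees, maximal depth, and the minimum samples a node
needs to split, expressed as a fraction of the training-pair count
(default 1e-6, i.e. 0.0001 %); the absolute value is floored at
scikit-learn's minimum of 2, which is semantically identical since a
single-sample node cannot split. Training pairs are drawn uniformly from
the hand region (background = everything in the hand except muscle); no
class reweighting.

The cross-validated grid search shuffles the datasets once with the run
seed, cuts them into k near-equal folds (k = 7 by default, reproducing a
6:1 train/validation cardinality ratio), trains on the k−1 training folds
and scores the validation fold by the Dice ratio, for every grid point in
order. The winner maximizes mean validation Dice; ties break toward fewer
trees, then smaller depth (the cheaper model). Feature tensors are cached
per (Gabor, ELBP) configuration, so grids that vary only forest
parameters reuse them.

## Post-processing

Dilation by an in-plane 4-connected radius-1 element (again no z extent),
island extraction discarding 26-connected components under 10 voxels, and
a Gaussian intensity trim: f(μ, σ) is fitted (maximum-likelihood, i.e.
sample mean/SD — equivalent to histogram curve fitting under a normal
model and parameter-free) and voxels outside μ ± 3σ are removed. The fit
uses the **pre-dilation** mask intensities: a dilation shell is typically
≥ 10 % of a compact 2D region (perimeter/area), and a single-Gaussian 3σ
rule breaks down at exactly 10 % contamination, so fitting on the dilated
mask would never remove the wrongly included voxels the step exists to
remove. With σ = 0 (or fewer than two mask voxels) the trim is skipped.

## Fat quantification

FF = fat/(fat+water)·1000‰ per voxel; zero-denominator voxels are set to
0 and counted. Registration is rigid (Euler 3D, geometric center
initialization), Mattes mutual information with 50 bins, seeded regular
sampling at 50 %, regular-step gradient descent (min step 1e-5,
relaxation 0.5) over a 2-level multiresolution pyramid — all exposed in
the config. Masks are resampled with nearest-neighbor interpolation so
they stay binary. Absolute fat content is defined as the fat-equivalent
volume Σ ff/1000 · voxel volume (mm³), the only unit-consistent reading;
mean fat fraction is reported in ‰ with % alongside.

## Evaluation metrics

Surfaces are mask voxels with at least one face-adjacent background
neighbor (the image border counts as background); distances are Euclidean
between voxel centers in mm. d_avg averages the nearest-surface distances
from A to B; h takes their maximum. As written, h is directed; both the
directed (default, automatic → reference) and the symmetric variant are
provided. Dice uses the standard 2|R∩M|/(|R|+|M|) with two empty masks
defined as 1. Precision: per-subject sample SD (n−1); RMS_SD is the RMS
of these SDs, CV the RMS of per-subject (SD/mean)·100 %; subjects with
zero mean are excluded from CV and reported.

## The phantom: what it emulates, what it does not

Each slice is a hand-shaped ellipse (background 10, tissue ≈ 510) with
circular cortical-bone inclusions (level 420) and elliptical muscle blobs
(level 450), arranged on interleaved three-fold star patterns whose
angular structure (a cos 3φ harmonic) is deliberately outside the span of
the low-order fields bias correction removes. Muscle cross-section tapers
as sin² towards the first and last slices, as real hand muscle does near
the VOI boundaries, and the per-slice blob scale is solved by bisection so
the muscle/hand volume ratio hits its target within ±0.01. Soft tissue
carries clipped Gaussian texture (SD 15) so it forms a broad histogram
hump rather than a third sharp peak; global additive noise (SD 4) widens
the bone and muscle peaks. An optional multiplicative bias field is a
low-order polynomial with up to ±(amplitude−1) deviation. The Dixon pair
is constructed by inverting the fat-fraction formula from a known FF map
(muscle: base 150‰ plus a 100‰ left-right gradient; other tissue 400‰),
so the pair and the truth map are consistent exactly.

Operator reanalysis is simulated as occasional ±1-slice misplacement of
each VOI boundary (probability 1/3 per boundary, mirroring that the
delimiting slices are usually unambiguous) plus removal of a small random
fraction of mask surface voxels (operators mostly delete wrongly included
tissue).

Not emulated: MR relaxometry, partial-volume mixing, ghosting and motion
artifacts, the raw in/out-of-phase echoes, wrist/forearm anatomy, and
realistic hand shape variability. Passing the phantom tests therefore
demonstrates that the pipeline's machinery is implemented correctly and
recovers known ground truth under the stated intensity statistics — not
that the shipped defaults reach any particular accuracy on patient data.

## Problem sizes and determinism

Tests and the acceptance suite run the phantom at a reduced 96×96×16 grid
(64×64×8 for quick unit tests); the full 320×320×64 acquisition grid is
available through the CLI (`simulate --full-grid`) and the spec. The
training cohort analogue is 14 phantoms with seeds 0–13; cross-validation
uses k = 7. One run seed fans out to per-stage seeds via a CRC32-based
derivation, keeping every stage individually reproducible; repeated runs
are bit-identical for masks and within float tolerance for volumes.

## Known limitations

* The polynomial bias model shares its function space with genuine
  low-order anatomy trends; the dominant-class windowing mitigates but
  cannot eliminate this for anatomies whose dominant class is not the
  majority of the hand.
* Peak detection requires a resolvable bimodal in-hand histogram; scans
  where bone and muscle peaks merge need manual peak override (supported
  in the API and CLI).
* The Gaussian trim assumes approximately normal muscle intensities; a
  strongly skewed muscle histogram would shift μ ± 3σ.
* Directed Hausdorff is asymmetric; the symmetric variant is provided but
  the default follows the formula as written (automatic → reference).
* The classifier is a plain random forest on hand-crafted features; no
  shape priors, so thin skin layers with muscle-like texture are the
  expected failure mode and the reason the workflow keeps an explicit
  operator-edit re-entry point.
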