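# Methods

## Acquisition model

A thick-slice stack acquired at angle θ about the phase-encode axis is
modeled as `y = A x + n` with `A = S · B · R`: rotation of the field of
view (R), convolution along the rotated slice-select axis with the slice
excitation profile (B), and sampling at the stack's voxel centers (S).
Conventions: world units are mm; voxel indices are 0-based and refer to
voxel centers; index boxes are half-open; the phase-encode axis is world
y and rotations act in the (x, z) plane; angles are normalized to
[0, 180°) because stacks at θ and θ + 180° sample identically; slice
spacing defaults to slice thickness (contiguous slices).

Because the rotation leaves y fixed, `A` factorizes exactly into a 2D
map applied to every (x, z) plane and an independent 1D resampling along
y.  Both factors are assembled once as sparse matrices from explicit
interpolation weights — Keys cubic convolution (a = −1/2) by default,
2-tap linear optionally — and the adjoint is the sparse transpose.  This
has two consequences worth knowing:

* the adjoint inner-product identity holds to rounding error by
  construction, and the dense-matrix oracle in the tests verifies the
  assembled operator itself;
* scipy's spline-prefiltered `map_coordinates` is deliberately *not*
  used inside the operator (its exact transpose is not available
  matrix-free); it is used for plain resampling outside the inverse
  problem (initialization, bias-field estimation, the interpolated
  single-stack comparator).

The slice profile is an ideal boxcar of width equal to the slice
thickness, discretized as `round(thickness/spacing)` equal taps one HR
voxel apart; a Gaussian profile with FWHM equal to the thickness is
available behind the `profile` switch.  Samples falling outside the
reconstruction FOV contribute zero (zero padding), so constants are
preserved only away from the FOV boundary.

## Reconstruction

The solver minimizes `Σ_k ‖y_k − A_k x‖² + λ‖x‖²` by conjugate gradient
on the SPD normal equations.  Defaults: relative-residual tolerance
1e-6, 100 iterations maximum, initialization with the voxelwise mean of
the cubically upsampled stacks (`zeros` optional), identity Tikhonov
operator (a first-difference operator is available).

**Regularization weight.**  `λ = 0.3 ×` the mean diagonal of
`Σ A_kᵀA_k` (computed cheaply from the separable factors), exposed in
`SRRConfig.lam`.  The scale-invariant form keeps the weight meaningful
across view counts and grid sizes.  The factor matters: the rotated-view
geometry samples the diagonal (x, z) frequency bands only weakly, so the
solution there behaves like `1/|H|`-amplified data; at the noise level
of the simulated studies (σ = 0.05 against unit background) weights two
orders of magnitude smaller leave a 4-view reconstruction with ≈4×
noise amplification in the agar region and ruin spot detection, while
the chosen scale corresponds to a Wiener-style `σ²/s²` with signal
deviation scale s ≈ 0.2.  CG on SPD normal equations is not guaranteed
monotone in the Euclidean residual; the recorded history is the honest
one and in practice decreases monotonically on these problems.

**Memory.**  The solver keeps five reconstruction-sized volumes (right
hand side, iterate, residual, search direction, operator-applied
direction) plus transient per-stack low-resolution buffers; all
persistent volumes go through an injectable allocation counter so the
contract is testable.  Per iteration it performs one forward and one
adjoint application per stack, so cost scales linearly with the number
of views and with the reconstruction voxel count — the basis of the
local-SRR speedup argument.

**Bias-field correction** (optional, for multi-coil data): all stacks
are co-resampled to a common grid, the voxelwise median is taken as the
consensus intensity, each stack's intensity-weighted smoothed ratio to
the consensus (Gaussian, default scale 5 mm) becomes its multiplicative
gain, clamped to [0.5, 2] and divided out on the stack's own grid.  The
consensus mask is eroded by two voxels because the partial-volume shell
carries resampling error, not gain information.  The estimator resolves
gain variations slower than the smoothing scale; the tests recover a
global ×2 gain and a 0.8→1.2 linear ramp to within 5%.

## Local (VOI) reconstruction

A VOI is an axis-aligned world-space box.  For local SRR the box is
padded by one full slice-kernel width plus three in-plane LR voxels,
snapped to the parent reconstruction grid, and the matching region
(plus another kernel half-width) is cropped out of every stack; the
solver then runs on the padded sub-problem.  Full-width padding — not
half — is required because the normal operator `AᵀA` couples voxels
across twice the forward kernel support; with it, the VOI core agrees
with the whole-volume reconstruction to ≈0.1% (the acceptance bound is
1%).  VOI localization routes: connected-component thresholding of a
signal volume; orthographic two-view back-projection of landmarks plus
a rigid Kabsch/Procrustes fit (the planar camera model is orthographic,
which makes the two-ray intersection closed-form; the views' mm-per-
pixel scale must be supplied); and PCA reformation of a binary shape
(principal frame with a deterministic sign convention: the first two
axes have positive first nonzero component, the third is their cross
product — degenerate, near-isotropic shapes still yield a valid basis).

## Digital bead phantom

The generator emulates a physical validation object: dark micro-beads
(low proton density) of graded size embedded in a bright agar cylinder.
The cylinder axis coincides with the rotation axis, so every rotated
view sees the same container and the resolution-anisotropic (x, z)
plane is also the transversal detection plane.  The scene is rendered
on a supersampled grid (factor 2 by default) and block-averaged, so
bead surfaces carry correct partial-volume intensities; ground-truth
labels are the 26-connected components of the *pre-blur* bead mask, so
detection is scored against physical objects rather than imaging
artifacts.  Bead placement and jitter are deterministic per seed.

Default conditions (96³ grid at 0.13 mm ≈ 12.5 mm FOV): agar intensity
1.0, bead intensity 0.05, noise σ = 0.05; acquisition at 0.1305 mm in
plane and 0.52 mm contiguous slices (anisotropy ≈ 4), views at
180°/K increments; 15 objects — twelve single beads with radii
0.07–0.30 mm and three three-bead clusters — spanning roughly 1–65
voxels with half the objects below ~8 voxels.  The size distribution is
deliberately weighted toward beads smaller than the slice thickness
(0.52 mm ≈ 4 voxels): that partial-volume regime is where thick-slice
imaging loses objects and where resolution recovery must prove itself;
a phantom of only large beads is detected perfectly even by the blurred
single-stack comparator and discriminates nothing.  Occasionally the
jitter merges or splits a cluster, so the realized object count can
differ from 15 by one or two; truth tables always reflect the realized
components.

What the phantom does *not* emulate: motion, susceptibility and
chemical-shift artifacts, Rician noise statistics, coil-array geometry,
meniscus/air bubbles, and k-space acquisition effects beyond the
slice-profile blur.  Passing the simulated study therefore demonstrates
correctness of the reconstruction and quantification chain under the
stated linear-Gaussian model, not robustness to real-scanner physics.

## Detection and quantification

Spot detection: per-transversal-slice grayscale bottom-hat (closing −
image) with a 5×5 square structuring element, thresholded at an
intensity percentile of the masked bottom-hat map, restricted to the
container mask eroded by 3 voxels (boundary artifacts are disregarded),
then 3D 26-connected components; components below a minimum size
(default 1, i.e. off) are dropped.  Matching is greedy one-to-one by
descending voxel overlap with ≥1-voxel overlap required; precision,
recall and `F = 2PR/(P+R)` follow, with P = R = F = 0 for an empty
detection against nonempty truth.

The threshold sweep evaluates a percentile grid (default
{90, 95, 97.5, 99, 99.5, 99.8, 99.9, 99.93, 99.95, 99.97, 99.99}) and
reports the F-maximizing threshold, ties broken toward the higher
percentile.  The upper end of the grid is dense because the optimum for
a sparse phantom sits in the top few tenths of a percent: ~230 bead
voxels inside a ~283k-voxel mask mean that even a perfect volume keeps
dozens of noise components at the 99.9th percentile.

Size stratification matches once on the full volumes, then per cutoff c
restricts scoring to truth objects larger than c voxels and excludes
unmatched detections of at most c voxels.  Matched detections follow
their truth object regardless of their own voxel count — at high
thresholds a large object is legitimately detected by only its few
strongest voxels, and penalizing that would conflate detection size
with detection success.

Spectral assessment: Hann-windowed 2D Fourier magnitude of a slice, with
the high-frequency energy fraction taken above half the reconstruction
Nyquist after mean removal.  Slices are taken in the (x, z) plane
(phase-encode coordinate fixed) because that is where the rotated-view
geometry adds resolution; in-plane slices of the unrotated view would
show no gain by construction.

## Study sizes and determinism

The simulated detection study runs at 96³ (≈0.9 M unknowns per
reconstruction); a full K ∈ {1, 2, 4} study including threshold sweeps
takes a few seconds, and the multi-seed acceptance checks use five
seeds.  All randomness (bead jitter, per-view noise) derives from
explicit integer seeds; per-view noise seeds are `seed + view index`.
Reconstruction itself is deterministic given its inputs.

## Known limitations

* Rigid, axis-aligned geometry only: rotations about one fixed axis,
  no oblique axes, no sub-pixel-shift acquisition schemes, no motion
  estimation during reconstruction.
* The single-stack comparator is an interpolation, not a
  deconvolution; it represents current practice, not the best possible
  single-view estimate.
* In-plane resolution is not super-resolved beyond the acquired
  in-plane sampling; gains are along the slice direction(s).
* The bias-field estimator assumes the consensus median is unbiased,
  i.e. fewer than half the stacks share the same gain defect.
* NIfTI I/O supports axis-aligned affines only.
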