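# locsrr — localized super-resolution reconstruction of thick-slice MRI

Pre-clinical whole-body MRI is usually acquired as 2D multi-slice
protocols with fine in-plane resolution and thick slices, because
T2-weighted 3D acquisitions at matched resolution take infeasibly long.
The thick slices cause strong partial-volume blurring along the
slice-select direction, which hides micro-structures such as early
metastatic lesions.  Super-resolution reconstruction (SRR) recovers an
isotropic high-resolution volume from several thick-slice stacks rotated
about the phase-encode axis — but at whole-body field of view the
inverse problem has tens of millions of unknowns, so this package
reconstructs *locally*: a volume of interest (VOI) is located (from a
planar optical signal, landmarks, or the principal axes of a segmented
shape), propagated into every rotated stack, and reconstructed on a
small padded grid with identical voxel values inside the VOI.

The package is aimed at small-animal imaging researchers and image
analysis developers who want a tested, scriptable implementation of the
full chain: forward acquisition model, regularized reconstruction, VOI
tooling, a digital bead-phantom generator, and the detection-based
quantification used to validate resolution recovery.

## Model

Each low-resolution stack is a linear view of the unknown isotropic
image **x**:

    y_k = A_k x + n_k,     k = 1 … K

where `A_k` rotates the field of view by θ_k = k·180°/K about the
phase-encode axis, convolves along the rotated slice axis with the slice
profile (boxcar of width equal to the slice thickness by default), and
samples on the coarse slice grid; `n_k` is i.i.d. Gaussian noise.  The
reconstruction solves the Tikhonov-regularized least-squares problem

    x̂ = argmin_x  Σ_k ‖y_k − A_k x‖² + λ‖x‖²

by conjugate gradient on the normal equations
`(Σ_k A_kᵀA_k + λI) x = Σ_k A_kᵀ y_k`.  `A_k` is assembled as a sparse
separable operator (the rotation acts only in the plane orthogonal to
the phase-encode axis), and the adjoint is its exact transpose, so
`⟨A x, y⟩ = ⟨x, Aᵀ y⟩` holds to rounding error.  The number of views
needed for full k-space coverage is `⌈π/2 · F⌉` with anisotropy factor
`F = slice thickness / in-plane voxel size`.

Detection-based quality scoring follows the bead-phantom methodology:
dark micro-objects are detected with a per-slice 5×5 bottom-hat filter,
thresholded at an intensity percentile, grouped in 3D, matched
one-to-one against ground truth, and summarized by
`F = 2PR/(P + R)`, optionally swept over thresholds and stratified by
object size.

## Worked example

`examples/03_phantom_detection_study.py` runs the simulated bead-phantom
experiment — a 96³ digital phantom at 0.13 mm with ~15 dark objects of
1–60 voxels in a bright agar cylinder, imaged as 1, 2 and 4 rotated
thick-slice stacks (0.1305 mm in plane, 0.52 mm slices, σ = 0.05):

```
truth objects: 14 sizes (voxels): [1, 1, 2, 2, 4, 4, 6, 8, 8, 14, 17, 19, 29, 52]

  volume  best pct precision  recall  F-score  HF energy
    1 LR     99.93     0.917   0.786    0.846     0.0045
 SRR (2)     99.93     0.737   1.000    0.848     0.0102
 SRR (4)     99.97     1.000   0.786    0.880     0.0186

all three volumes detect perfectly above 4 voxels
```

Reading the numbers: the interpolated single stack (`1 LR`) misses the
smallest beads; adding views raises the best-threshold F-score and
roughly doubles the high-frequency spectral energy per doubling of K,
i.e. the extra views contribute genuine resolution, not just SNR.  Only
objects of a few voxels are ever missed — all three volumes detect
perfectly once the smallest objects are excluded.

The other examples cover view planning (`01`), the forward model and its
adjoint (`02`), local-vs-whole-volume reconstruction (`04`), and
landmark back-projection/VOI localization (`05`).

## Command line

Every pipeline stage is also a CLI subcommand driven by a YAML config:

```sh
locsrr phantom    --config run.yaml --seed 1 --out out/
locsrr simulate   --config run.yaml --seed 1 --out out/
locsrr reconstruct --config run.yaml --out out/
locsrr evaluate   --config run.yaml --out out/
```

Volumes are NIfTI with spacing/origin in the affine; geometries and VOIs
are JSON; sweep and size-stratified tables are CSV.  Each stage writes a
manifest recording parameters, seed and output hashes, so every artifact
is regenerable from config + seed.

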