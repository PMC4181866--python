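"""The linear thick-slice acquisition operator and its exact adjoint.

A low-resolution stack acquired at angle θ about the phase-encode axis is
modeled as ``y_k = A_k x + n_k``: the high-resolution scene is sampled in
the rotated frame, blurred along the rotated slice axis by the slice
excitation profile, and read out on the coarse slice grid, plus i.i.d.
Gaussian noise.

Because the rotation leaves the phase-encode (y) axis fixed, ``A_k``
factorizes into a 2D map acting on every (x, z) plane identically and an
independent 1D resampling along y.  Both factors are assembled once as
explicit sparse matrices; the adjoint is their exact transpose, so the
inner-product identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to rounding error by
construction.

Interpolation uses explicit convolution-kernel weights (Keys cubic by
default, linear optional) rather than a prefiltered B-spline, so that the
same weights define both the forward and the adjoint.  Samples that fall
outside the high-resolution field of view contribute zero (zero padding);
consequently a constant image maps to a constant only away from the FOV
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .geometry import AcquisitionGeometry, VoxelGrid, rotation_about_y

__all__ = [
    "HRImage",
    "LRStack",
    "ForwardOperator",
    "slice_profile_kernel",
    "apply_forward",
    "apply_adjoint",
    "add_noise",
]


@dataclass
class HRImage:
    """A scalar volume on an isotropic high-resolution grid."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not self.grid.is_isotropic():
            raise ValueError("HR grid must be isotropic")

    @property
    def spacing_mm(self) -> float:
        return self.grid.spacing[0]

    def copy(self) -> "HRImage":
        return HRImage(self.grid, self.data.copy())


@dataclass
class LRStack:
    """One thick-slice acquisition: data on the LR grid plus its geometry.

    ``origin`` is the acquisition-frame position (mm) of voxel (0,0,0);
    ``None`` means the stack is centered on the rotation axis.  Cropped
    stacks (VOI extraction) carry an explicit off-center origin.
    """

    geometry: AcquisitionGeometry
    data: np.ndarray
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"stack shape {self.data.shape} != geometry shape "
                f"{self.geometry.shape}"
            )

    def grid(self) -> VoxelGrid:
        """Sampling grid in the (unrotated) acquisition frame."""
        if self.origin is None:
            return self.geometry.grid()
        return VoxelGrid(self.geometry.shape, self.geometry.spacing, self.origin)

    def copy(self) -> "LRStack":
        return LRStack(self.geometry, self.data.copy(), self.origin)


def slice_profile_kernel(
    thickness_mm: float, hr_spacing_mm: float, profile: str = "boxcar"
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize the slice excitation profile on the HR grid.

    Returns ``(taps, offsets_mm)``: tap weights summing to one and the
    signed distances (mm) of the taps from the slice center along the
    slice-select axis.

    The default ``boxcar`` profile models an ideal rectangular excitation
    of width ``thickness_mm``: ``round(thickness / hr_spacing)`` equal
    taps spaced one HR voxel apart.  ``gaussian`` models a smooth profile
    with FWHM equal to the slice thickness.
    """
    if thickness_mm <= 0 or hr_spacing_mm <= 0:
        raise ValueError("thickness and spacing must be positive")
    if thickness_mm < hr_spacing_mm:
        raise ValueError("slice thickness must be >= HR spacing")
    if profile == "boxcar":
        n = max(1, int(round(thickness_mm / hr_spacing_mm)))
        offsets = (np.arange(n) - (n - 1) / 2.0) * hr_spacing_mm
        taps = np.full(n, 1.0 / n)
    elif profile == "gaussian":
        sigma = thickness_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM = thickness
        m = max(1, int(np.ceil(3.0 * sigma / hr_spacing_mm)))
        offsets = np.arange(-m, m + 1) * hr_spacing_mm
        taps = np.exp(-0.5 * (offsets / sigma) ** 2)
        taps /= taps.sum()
    else:
        raise ValueError(f"unknown slice profile {profile!r}")
    return taps, offsets


def _kernel_weights(frac: np.ndarray, order: int) -> np.ndarray:
    """Interpolation weights for fractional offsets ``frac`` in [0, 1).

    Returns an array of shape ``frac.shape + (order + 1,)`` with weights for
    the support points ``floor(u) - order//2 + j``.  Both kernels reproduce
    constants exactly (weights sum to 1).
    """
    if order == 1:
        return np.stack([1.0 - frac, frac], axis=-1)
    if order == 3:
        # Keys cubic convolution, a = -1/2
        a = -0.5
        t = frac[..., None] - np.array([-1.0, 0.0, 1.0, 2.0])
        at = np.abs(t)
        w = np.where(
            at < 1.0,
            (a + 2.0) * at**3 - (a + 3.0) * at**2 + 1.0,
            np.where(at < 2.0, a * at**3 - 5.0 * a * at**2 + 8.0 * a * at - 4.0 * a, 0.0),
        )
        return w
    raise ValueError(f"interpolation order must be 1 or 3, got {order}")


def _interp_stencil(u: np.ndarray, n: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Support columns and weights for sampling a length-n axis at positions u.

    Returns ``(cols, w)`` of shape ``(len(u), order+1)``.  Out-of-range
    support points get zero weight (zero padding) and a clipped column
    index, so the arrays stay rectangular for vectorized assembly.
    """
    u = np.asarray(u, dtype=float).ravel()
    base = np.floor(u).astype(int)
    frac = u - base
    w = _kernel_weights(frac, order)  # (m, order+1)
    offs = np.array([-1, 0, 1, 2]) if order == 3 else np.array([0, 1])
    cols = base[:, None] + offs[None, :]
    invalid = (cols < 0) | (cols >= n)
    w = np.where(invalid, 0.0, w)
    cols = np.clip(cols, 0, n - 1)
    return cols, w


def _interp_matrix_1d(u: np.ndarray, n: int, order: int) -> sp.csr_matrix:
    """Sparse (len(u), n) matrix sampling a length-n sequence at positions u."""
    cols, w = _interp_stencil(u, n, order)
    rows = np.broadcast_to(np.arange(cols.shape[0])[:, None], cols.shape)
    mat = sp.coo_matrix(
        (w.ravel(), (rows.ravel(), cols.ravel())), shape=(cols.shape[0], n)
    )
    return mat.tocsr()


class ForwardOperator:
    """The acquisition operator ``A_k`` for one rotated thick-slice stack.

    Maps an :class:`HRImage` on ``hr_grid`` to an :class:`LRStack` with
    ``geometry`` (optionally off-center via ``lr_origin``).  Linear by
    construction; :meth:`adjoint` applies the exact transpose.
    """

    def __init__(
        self,
        hr_grid: VoxelGrid,
        geometry: AcquisitionGeometry,
        lr_origin: tuple[float, float, float] | None = None,
        profile: str = "boxcar",
        order: int = 3,
    ) -> None:
        if not hr_grid.is_isotropic():
            raise ValueError("HR grid must be isotropic")
        self.hr_grid = hr_grid
        self.geometry = geometry
        self.lr_origin = lr_origin
        self.profile = profile
        self.order = order
        h = hr_grid.spacing[0]
        self.taps, self.tap_offsets = slice_profile_kernel(
            geometry.thickness_mm, h, profile
        )
        self._build()

    # -- assembly -----------------------------------------------------------
    def _lr_grid(self) -> VoxelGrid:
        if self.lr_origin is None:
            return self.geometry.grid()
        return VoxelGrid(self.geometry.shape, self.geometry.spacing, self.lr_origin)

    def _build(self) -> None:
        g = self.geometry
        lr = self._lr_grid()
        hr = self.hr_grid
        nx, ny, nz = hr.shape
        mx, my, mz = lr.shape
        R = rotation_about_y(g.angle_deg)

        # acquisition-frame sample coordinates in the (x', z') plane
        xp = lr.axis_coordinates(0)
        zp = lr.axis_coordinates(2)
        XP, ZP = np.meshgrid(xp, zp, indexing="ij")  # (mx, mz)

        hx = hr.spacing[0]
        rows_plane = mx * mz
        cols_plane = nx * nz
        nsup = self.order + 1
        blocks = []
        row_ids = np.arange(rows_plane)
        for tap, off in zip(self.taps, self.tap_offsets):
            # world coordinates of the blurred sample points
            wx = R[0, 0] * XP + R[0, 2] * (ZP + off)
            wz = R[2, 0] * XP + R[2, 2] * (ZP + off)
            ux = ((wx - hr.origin[0]) / hx).ravel()
            uz = ((wz - hr.origin[2]) / hr.spacing[2]).ravel()
            cx, wxw = _interp_stencil(ux, nx, self.order)  # (m, nsup)
            cz, wzw = _interp_stencil(uz, nz, self.order)
            # separable 2D stencil: outer product per sample point
            w2 = tap * wxw[:, :, None] * wzw[:, None, :]  # (m, nsup, nsup)
            c2 = cx[:, :, None] * nz + cz[:, None, :]
            r2 = np.broadcast_to(row_ids[:, None, None], w2.shape)
            blocks.append(
                sp.coo_matrix(
                    (w2.ravel(), (r2.ravel(), c2.ravel())),
                    shape=(rows_plane, cols_plane),
                ).tocsr()
            )
        M = blocks[0]
        for b in blocks[1:]:
            M = M + b
        self._M = M.tocsr()
        self._M.sum_duplicates()

        # y-axis resampling (rotation leaves y fixed)
        uy = (lr.axis_coordinates(1) - hr.origin[1]) / hr.spacing[1]
        self._P = _interp_matrix_1d(uy, ny, self.order)

    # -- application --------------------------------------------------------
    def __call__(self, x: HRImage) -> LRStack:
        return self.apply(x)

    def apply(self, x: HRImage) -> LRStack:
        if x.grid.shape != self.hr_grid.shape:
            raise ValueError(
                f"image grid {x.grid.shape} does not match operator grid "
                f"{self.hr_grid.shape}"
            )
        nx, ny, nz = self.hr_grid.shape
        mx, my, mz = self.geometry.shape
        X2 = x.data.transpose(0, 2, 1).reshape(nx * nz, ny)
        Y2 = self._M @ X2  # (mx*mz, ny_hr)
        Y2 = (self._P @ Y2.T).T  # resample y axis -> (mx*mz, my)
        out = np.asarray(Y2).reshape(mx, mz, my).transpose(0, 2, 1)
        return LRStack(self.geometry, out, self.lr_origin)

    def adjoint(self, y: LRStack) -> HRImage:
        if y.data.shape != self.geometry.shape:
            raise ValueError(
                f"stack shape {y.data.shape} does not match operator geometry "
                f"{self.geometry.shape}"
            )
        nx, ny, nz = self.hr_grid.shape
        mx, my, mz = self.geometry.shape
        Y2 = y.data.transpose(0, 2, 1).reshape(mx * mz, my)
        X2 = self._M.T @ (self._P.T @ Y2.T).T  # (nx*nz, ny_hr)
        out = np.asarray(X2).reshape(nx, nz, ny).transpose(0, 2, 1)
        return HRImage(self.hr_grid, out)

    @property
    def n_lr_voxels(self) -> int:
        return int(np.prod(self.geometry.shape))


def apply_forward(op: ForwardOperator, x: HRImage) -> LRStack:
    """Noise-free acquisition ``y = A x``."""
    return op.apply(x)


def apply_adjoint(op: ForwardOperator, y: LRStack) -> HRImage:
    """Exact adjoint ``Aᵀ y`` (Euclidean inner products on both grids)."""
    return op.adjoint(y)


def add_noise(y: LRStack, sigma: float, seed: int) -> LRStack:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return y.copy()
    rng = np.random.default_rng(seed)
    noisy = y.data + rng.normal(0.0, sigma, size=y.data.shape)
    return LRStack(replace(y.geometry, sigma=float(sigma)), noisy, y.origin)
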