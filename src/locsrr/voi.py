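"""Volume-of-interest localization, registration, propagation and extraction.

The point of local SRR is to reconstruct only a small box around a
structure of interest instead of the whole body.  This module locates
such boxes (from a planar optical signal or from the principal axes of a
segmented shape), registers the frames they live in (landmark
back-projection + rigid Procrustes), propagates a box through the known
per-acquisition transforms, and crops the matching region out of every
low-resolution stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import CoverageError, DegenerateGeometryError
from .forward import LRStack
from .geometry import RigidTransform, VoxelGrid, rotation_about_y

__all__ = [
    "VOI",
    "PlanarView",
    "backproject_landmark",
    "fit_rigid_landmarks",
    "voi_from_signal",
    "propagate_and_extract_voi",
    "pca_reformation",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VOI:
    """Axis-aligned world-space box with an extraction margin (mm)."""

    min_mm: tuple[float, float, float]
    max_mm: tuple[float, float, float]
    margin_mm: float = 0.0
    frame: str = "world"

    def __post_init__(self) -> None:
        lo = tuple(float(v) for v in self.min_mm)
        hi = tuple(float(v) for v in self.max_mm)
        if any(h < l for l, h in zip(lo, hi)):
            raise ValueError(f"VOI max {hi} must be >= min {lo} componentwise")
        if self.margin_mm < 0:
            raise ValueError("margin must be >= 0")
        object.__setattr__(self, "min_mm", lo)
        object.__setattr__(self, "max_mm", hi)

    @property
    def corners(self) -> np.ndarray:
        """The 8 corner points, shape (8, 3)."""
        lo, hi = np.asarray(self.min_mm), np.asarray(self.max_mm)
        idx = np.array(np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij"))
        idx = idx.reshape(3, 8).T
        return np.where(idx == 0, lo, hi)

    def expanded(self, pad_mm: float) -> "VOI":
        lo = tuple(v - pad_mm for v in self.min_mm)
        hi = tuple(v + pad_mm for v in self.max_mm)
        return VOI(lo, hi, self.margin_mm, self.frame)

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame": self.frame,
                "min_mm": list(self.min_mm),
                "max_mm": list(self.max_mm),
                "margin_mm": self.margin_mm,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "VOI":
        d = json.loads(text)
        return cls(
            tuple(d["min_mm"]), tuple(d["max_mm"]), d.get("margin_mm", 0.0),
            d.get("frame", "world"),
        )


@dataclass(frozen=True)
class PlanarView:
    """A 2D planar (optical) image taken at a known angle about the
    subject's long axis; pixel coordinates are (u, v) in mm with v along
    the rotation axis."""

    image: np.ndarray
    angle_deg: float
    pixel_mm: float

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ValueError("pixel spacing must be > 0")


def _view_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u axis, v axis, ray direction) of an orthographic view.

    The view at 0° looks along -z: u is the world x axis, v the rotation
    (y) axis.  Rotating the camera by θ about y rotates u and the ray.
    """
    R = rotation_about_y(angle_deg)
    u = R @ np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    ray = R @ np.array([0.0, 0.0, 1.0])
    return u, v, ray


def project_point(point: np.ndarray, angle_deg: float) -> np.ndarray:
    """Orthographic (u, v) image coordinates of a 3D world point."""
    u, v, _ = _view_axes(angle_deg)
    p = np.asarray(point, dtype=float)
    return np.array([u @ p, v @ p])


def backproject_landmark(
    obs: list[tuple[float, np.ndarray]] | list[tuple[float, tuple[float, float]]],
) -> np.ndarray:
    """Intersect the orthographic back-projection rays of one landmark.

    ``obs`` holds ``(view_angle_deg, (u_mm, v_mm))`` for two views at
    distinct angles.  Each observation constrains the 3D point to a line;
    the least-squares intersection solves the stacked normal equations
    and is exact when the rays meet.
    """
    if len(obs) < 2:
        raise ValueError("need observations in at least two views")
    angles = [a for a, _ in obs]
    for i in range(len(angles)):
        for j in range(i + 1, len(angles)):
            if abs((angles[i] - angles[j]) % 180.0) < 1e-9 or abs(
                (angles[i] - angles[j]) % 180.0
            ) > 180.0 - 1e-9:
                raise DegenerateGeometryError(
                    f"views at {angles[i]}° and {angles[j]}° are parallel; "
                    "no depth information"
                )
    rows, rhs = [], []
    for angle, uv in obs:
        u_ax, v_ax, _ = _view_axes(angle)
        u, v = float(uv[0]), float(uv[1])
        rows.extend([u_ax, v_ax])
        rhs.extend([u, v])
    A = np.asarray(rows)
    b = np.asarray(rhs)
    point, *_ = np.linalg.lstsq(A, b, rcond=None)
    return point


def fit_rigid_landmarks(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid (Procrustes/Kabsch) fit T(m_i) ≈ f_i.

    Requires at least three non-collinear point pairs; returns a proper
    rotation (det +1) plus translation.
    """
    m = np.asarray(moving, dtype=float)
    f = np.asarray(fixed, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("moving and fixed must both be (N, 3)")
    if m.shape[0] < 3:
        raise ValueError("need at least three landmark pairs")
    mc = m - m.mean(axis=0)
    fc = f - f.mean(axis=0)
    s = np.linalg.svd(mc, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "landmarks are collinear; rotation about the line is unconstrained"
        )
    H = mc.T @ fc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = f.mean(axis=0) - R @ m.mean(axis=0)
    return RigidTransform(R, t)


def voi_from_signal(
    image: np.ndarray,
    grid: VoxelGrid,
    threshold: float,
    margin_mm: float = 0.0,
) -> list[VOI]:
    """One VOI per connected suprathreshold component (26-connectivity).

    Typical usage thresholds a raw optical-signal volume; each
    blob's world bounding box, expanded by ``margin_mm``, becomes a VOI.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = np.asarray(image) > threshold
    labels, n = ndimage.label(mask, structure=_CONN26)
    vois = []
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        lo_idx = np.array([s.start for s in sl], dtype=float)
        hi_idx = np.array([s.stop - 1 for s in sl], dtype=float)
        lo = origin + lo_idx * spacing - margin_mm
        hi = origin + hi_idx * spacing + margin_mm
        vois.append(VOI(tuple(lo), tuple(hi), margin_mm))
    return vois


def propagate_and_extract_voi(
    voi: VOI,
    stacks: list[LRStack],
    transforms: list[RigidTransform] | None = None,
    pad_policy: str = "clip",
    extra_pad_mm: float | None = None,
) -> list[LRStack]:
    """Propagate a reference-frame VOI to every stack and crop it out.

    ``transforms[k]`` maps the VOI's reference frame into stack k's
    acquisition frame; ``None`` uses each stack's own rotation (reference
    frame = world).  The 8 VOI corners are mapped, their axis-aligned
    bounding box is expanded by the VOI margin plus half the slice-kernel
    support (``extra_pad_mm`` overrides the default of half a slice
    thickness plus two in-plane voxels), and the stack is cropped on voxel
    boundaries.

    ``pad_policy`` controls partial coverage: ``"clip"`` crops what is
    available, ``"error"`` raises :class:`CoverageError`.
    """
    if transforms is None:
        transforms = [
            RigidTransform(rotation_about_y(s.geometry.angle_deg), np.zeros(3)).inverse()
            for s in stacks
        ]
    if len(transforms) != len(stacks):
        raise ValueError("need exactly one transform per stack")
    if pad_policy not in ("clip", "error"):
        raise ValueError(f"pad_policy must be 'clip' or 'error', got {pad_policy!r}")

    out = []
    for k, (s, T) in enumerate(zip(stacks, transforms)):
        g = s.geometry
        pad = (
            extra_pad_mm
            if extra_pad_mm is not None
            else g.thickness_mm / 2.0 + 2.0 * g.in_plane_mm
        )
        corners_local = T.apply(voi.corners)
        lo = corners_local.min(axis=0) - voi.margin_mm - pad
        hi = corners_local.max(axis=0) + voi.margin_mm + pad
        sgrid = s.grid()
        lo_idx = np.floor(sgrid.world_to_voxel(lo)).astype(int)
        hi_idx = np.ceil(sgrid.world_to_voxel(hi)).astype(int) + 1  # half-open
        shape = np.asarray(sgrid.shape)
        if np.any(hi_idx <= 0) or np.any(lo_idx >= shape):
            raise CoverageError(f"VOI lies entirely outside stack {k}")
        clipped_lo = np.clip(lo_idx, 0, shape)
        clipped_hi = np.clip(hi_idx, 0, shape)
        if pad_policy == "error" and (
            np.any(clipped_lo != lo_idx) or np.any(clipped_hi != hi_idx)
        ):
            raise CoverageError(
                f"VOI footprint extends beyond the FOV of stack {k}"
            )
        sl = tuple(slice(int(a), int(b)) for a, b in zip(clipped_lo, clipped_hi))
        cropped = s.data[sl]
        new_origin = tuple(
            sgrid.origin[i] + clipped_lo[i] * sgrid.spacing[i] for i in range(3)
        )
        new_geom = replace(g, shape=cropped.shape)
        out.append(LRStack(new_geom, cropped, new_origin))
    return out


def pca_reformation(
    mask: np.ndarray, grid: VoxelGrid
) -> tuple[RigidTransform, VOI]:
    """Principal-axes frame and tight oriented box of a binary shape.

    Eigen-decomposes the covariance of the shape's voxel-center world
    coordinates.  The returned transform maps world points into the
    principal frame (largest-variance axis first, right-handed); the VOI
    is the tight bounding box of the shape in that frame.  Sign
    convention: each of the first two axes is flipped so its first
    nonzero component is positive; the third axis is their cross product.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    idx = np.argwhere(mask).astype(float)
    pts = idx * np.asarray(grid.spacing) + np.asarray(grid.origin)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T) if len(pts) > 1 else np.eye(3)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows = principal axes, descending variance
    for i in range(2):
        nz = np.nonzero(np.abs(axes[i]) > 1e-12)[0]
        if len(nz) and axes[i][nz[0]] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    T = RigidTransform(axes, -axes @ centroid)
    local = T.apply(pts)
    half = np.asarray(grid.spacing) / 2.0
    lo = local.min(axis=0) - np.max(half)
    hi = local.max(axis=0) + np.max(half)
    return T, VOI(tuple(lo), tuple(hi), frame="principal")
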