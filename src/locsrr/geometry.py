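"""Grids, rigid transforms, and acquisition-geometry bookkeeping.

Conventions used throughout the package:

* World coordinates are in millimetres; voxel indices are 0-based and a
  voxel's coordinate refers to its **center**; index-space boxes are
  half-open.
* The unrotated reference frame has axes (x = readout, y = phase-encode,
  z = slice).  Slice stacks are rotated about the phase-encode axis, i.e.
  world ``y``; the rotation therefore acts in the (x, z) plane.
* Angles are stored in degrees and normalised to [0, 180), since a stack
  acquired at θ+180° samples the scene identically to one at θ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VoxelGrid",
    "RigidTransform",
    "AcquisitionGeometry",
    "AcquisitionSet",
    "make_acquisition_set",
    "optimal_view_count",
    "world_voxel_map",
    "rotation_about_y",
    "total_acquisition_time",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); all extents >= 1.
    spacing
        Voxel size in mm along each axis; all > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("VoxelGrid is three-dimensional")
        if any(n < 1 for n in shape):
            raise ValueError(f"grid extents must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def centered(
        cls, shape: tuple[int, int, int], spacing: tuple[float, float, float] | float
    ) -> "VoxelGrid":
        """Grid whose world center coincides with the world origin."""
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(tuple(shape), tuple(spacing), origin)

    @property
    def num_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def fov(self) -> tuple[float, float, float]:
        """Physical extent (mm) covered by the voxels, edge to edge."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def is_isotropic(self, tol: float = 1e-9) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= tol and abs(s[1] - s[2]) <= tol

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Continuous voxel indices -> world mm (grid frame, no rotation)."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (tol 1e-9)")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or many (N, 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def rotation_about_y(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the phase-encode (y) axis.

    Maps acquisition-frame coordinates into world coordinates: the rotated
    readout axis is ``(cos θ, 0, -sin θ)`` and the rotated slice axis is
    ``(sin θ, 0, cos θ)``.
    """
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of one thick-slice acquisition.

    ``angle_deg`` is the rotation about the phase-encode axis; the slice
    stack has fine ``in_plane_mm`` resolution in the (readout,
    phase-encode) plane and thick slices (``thickness_mm``) stacked at
    ``gap_mm`` intervals along the rotated slice axis.  ``sigma`` is the
    standard deviation of the additive Gaussian acquisition noise.
    """

    angle_deg: float
    in_plane_mm: float
    thickness_mm: float
    shape: tuple[int, int, int]
    gap_mm: float | None = None  # slice spacing; defaults to thickness (contiguous)
    sigma: float = 0.0

    def __post_init__(self) -> None:
        angle = float(self.angle_deg) % 180.0
        object.__setattr__(self, "angle_deg", angle)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.gap_mm is None:
            object.__setattr__(self, "gap_mm", float(self.thickness_mm))
        if self.in_plane_mm <= 0 or self.thickness_mm <= 0 or self.gap_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.thickness_mm < self.in_plane_mm:
            raise ValueError(
                "slice thickness must be >= in-plane spacing "
                f"({self.thickness_mm} < {self.in_plane_mm})"
            )
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid LR grid shape {self.shape}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Sampling spacing of the LR grid (readout, phase, slice)."""
        return (self.in_plane_mm, self.in_plane_mm, float(self.gap_mm))

    @property
    def anisotropy_factor(self) -> float:
        """F = slice thickness / in-plane spacing."""
        return self.thickness_mm / self.in_plane_mm

    def grid(self) -> VoxelGrid:
        """LR sampling grid in the (unrotated) acquisition frame, centered."""
        return VoxelGrid.centered(self.shape, self.spacing)

    def frame(self) -> RigidTransform:
        """Acquisition frame -> world transform (rotation about y)."""
        return RigidTransform(rotation_about_y(self.angle_deg), np.zeros(3))

    def with_angle(self, angle_deg: float) -> "AcquisitionGeometry":
        return replace(self, angle_deg=angle_deg)


@dataclass(frozen=True)
class AcquisitionSet:
    """An ordered multi-orientation acquisition protocol."""

    geometries: tuple[AcquisitionGeometry, ...]

    def __post_init__(self) -> None:
        geoms = tuple(self.geometries)
        if len(geoms) < 1:
            raise ValueError("an acquisition set needs at least one view")
        object.__setattr__(self, "geometries", geoms)

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(self.geometries)

    def __getitem__(self, i: int) -> AcquisitionGeometry:
        return self.geometries[i]

    @property
    def angles_deg(self) -> list[float]:
        return [g.angle_deg for g in self.geometries]


def make_acquisition_set(K: int, base: AcquisitionGeometry) -> AcquisitionSet:
    """Evenly rotated protocol: K views at angles i * 180/K degrees.

    Rotating in increments of 180°/K about the phase-encode axis gives the
    most even angular coverage of the slice direction (views at θ and
    θ+180° are redundant).
    """
    if not isinstance(K, (int, np.integer)) or K < 1:
        raise ValueError(f"view count K must be a positive integer, got {K!r}")
    if base.angle_deg != 0.0:
        raise ValueError("base geometry must have angle 0")
    return AcquisitionSet(
        tuple(base.with_angle(i * 180.0 / K) for i in range(K))
    )


def optimal_view_count(F: float) -> int:
    """Number of rotated views giving optimal k-space coverage: ⌈π/2 · F⌉.

    ``F`` is the anisotropy factor (slice thickness over in-plane voxel
    size).  Using more views than this does not add resolution, only a
    modest amount of SNR.
    """
    F = float(F)
    if not math.isfinite(F) or F < 1.0:
        raise ValueError(f"anisotropy factor must be >= 1, got {F}")
    return int(math.ceil(math.pi / 2.0 * F))


def world_voxel_map(
    grid: VoxelGrid,
    transform: RigidTransform,
    point: np.ndarray,
    direction: str = "to-world",
) -> np.ndarray:
    """Map between continuous voxel indices and world coordinates.

    ``transform`` carries the grid's frame into the world (grid-frame mm ->
    world mm).  ``direction`` is ``"to-world"`` (voxel index -> world mm) or
    ``"to-voxel"`` (world mm -> voxel index).  Out-of-grid continuous
    coordinates are legal; callers clip.
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    if direction == "to-world":
        return transform.apply(grid.voxel_to_world(p))
    if direction == "to-voxel":
        return grid.world_to_voxel(transform.inverse().apply(p))
    raise ValueError(f"direction must be 'to-world' or 'to-voxel', got {direction!r}")


def total_acquisition_time(K: int, minutes_per_stack: float) -> float:
    """Total scan time of a K-view protocol, in minutes."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return K * float(minutes_per_stack)
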