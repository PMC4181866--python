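"""NIfTI volume I/O and geometry/VOI serialization.

Volumes are stored as NIfTI-1 with the grid spacing and origin carried in
the affine (axis-aligned, RAS-like: affine = diag(spacing) with the
translation at the origin of voxel (0,0,0)).  Array axis order is
(x, y, z) matching the package's (readout, phase-encode, slice)
convention for unrotated frames.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, UnsupportedOrientationError
from .forward import LRStack
from .geometry import AcquisitionGeometry, VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_geometries",
    "write_geometries",
    "read_stack",
    "write_stack",
    "sha256_file",
]


def write_volume(path: str | Path, data: np.ndarray, grid: VoxelGrid) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI volume; returns (data, grid).

    Only axis-aligned (diagonal-affine) orientations are supported; a
    rotated or sheared affine raises :class:`UnsupportedOrientationError`.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except UnsupportedOrientationError:
        raise
    except Exception as exc:  # nibabel raises several parse-error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise UnsupportedOrientationError(
            f"non-axis-aligned affine in {path}; resample before loading"
        )
    spacing = tuple(float(abs(d)) for d in np.diag(rot))
    origin = tuple(float(v) for v in affine[:3, 3])
    return data, VoxelGrid(data.shape, spacing, origin)


def _geom_dict(geo: AcquisitionGeometry, origin=None) -> dict:
    d = {
        "angle_deg": geo.angle_deg,
        "in_plane_mm": geo.in_plane_mm,
        "thickness_mm": geo.thickness_mm,
        "gap_mm": geo.gap_mm,
        "shape": list(geo.shape),
        "sigma": geo.sigma,
    }
    if origin is not None:
        d["origin_mm"] = list(origin)
    return d


def write_geometries(path: str | Path, stacks: list[LRStack]) -> None:
    entries = [_geom_dict(s.geometry, s.origin) for s in stacks]
    Path(path).write_text(json.dumps({"stacks": entries}, indent=2))


def read_geometries(path: str | Path) -> list[tuple[AcquisitionGeometry, tuple | None]]:
    try:
        doc = json.loads(Path(path).read_text())
        out = []
        for e in doc["stacks"]:
            geo = AcquisitionGeometry(
                angle_deg=e["angle_deg"],
                in_plane_mm=e["in_plane_mm"],
                thickness_mm=e["thickness_mm"],
                gap_mm=e.get("gap_mm"),
                shape=tuple(e["shape"]),
                sigma=e.get("sigma", 0.0),
            )
            origin = tuple(e["origin_mm"]) if "origin_mm" in e else None
            out.append((geo, origin))
        return out
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse geometry file {path}: {exc}") from exc


def write_stack(path: str | Path, stack: LRStack) -> None:
    write_volume(path, stack.data, stack.grid())


def read_stack(path: str | Path, geometry: AcquisitionGeometry) -> LRStack:
    data, grid = read_volume(path)
    if data.shape != geometry.shape:
        raise FormatError(
            f"stack {path} shape {data.shape} != geometry shape {geometry.shape}"
        )
    return LRStack(geometry, data, grid.origin)


def sha256_file(path: str | Path) -> str:
    hsh = hashlib.sha256()
    hsh.update(Path(path).read_bytes())
    return hsh.hexdigest()
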