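"""Containers and I/O for binary vessel volumes and centerline files.

All world coordinates are in millimetres.  Voxel *centers* carry world
coordinates: the volume ``origin`` is the mm position of voxel index
``(0, 0, 0)`` and index axis order is ``(i, j, k) <-> (x, y, z)`` with no
permutation.  Only axis-aligned, positive, isotropic NIfTI affines are
supported; this tool does not reorient.

Centerline text files follow the common challenge layout: one point per
line, ``x y z r`` (whitespace separated, mm), ``#`` comments allowed and
extra columns ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    CenterlineParseError,
    InvalidCenterlineError,
    OutOfBoundsError,
    UnsupportedOrientationError,
)

__all__ = [
    "ReferenceCenterline",
    "BinaryVolume",
    "Centerline",
    "read_reference",
    "write_reference",
    "read_volume",
    "write_volume",
    "voxel_to_mm",
    "mm_to_voxel",
    "round_half_away",
]

#: Default isotropic voxel edge length (mm); roughly the in-plane
#: resolution of the synthetic coronary volumes this package emulates.
DEFAULT_VOXEL_SIZE = 0.1


def round_half_away(t: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero.

    A tiny epsilon absorbs binary-representation error so that values such
    as ``0.25 / 0.1`` (stored as 2.4999...96) still round up to 3.
    """
    t = np.asarray(t, dtype=float)
    return np.sign(t) * np.floor(np.abs(t) + 0.5 + 1e-9)


@dataclasses.dataclass(frozen=True)
class ReferenceCenterline:
    """Ordered ground-truth centerline samples ``(x, y, z)`` with radii (mm)."""

    xyz: np.ndarray
    radii: np.ndarray
    label: str = ""

    def __post_init__(self):
        xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        radii = np.asarray(self.radii, dtype=float).ravel()
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise InvalidCenterlineError("points must be an (n, 3) array")
        if xyz.shape[0] != radii.shape[0]:
            raise InvalidCenterlineError("points and radii length mismatch")
        if xyz.shape[0] < 2:
            raise InvalidCenterlineError("a centerline needs at least 2 points")
        if not np.all(radii > 0):
            raise InvalidCenterlineError("all radii must be positive")
        if np.any(np.all(np.diff(xyz, axis=0) == 0.0, axis=1)):
            raise InvalidCenterlineError("consecutive points must be distinct")
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "radii", radii)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.xyz, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])


@dataclasses.dataclass(frozen=True)
class BinaryVolume:
    """3D occupancy grid with isotropic voxel size and world origin (mm)."""

    grid: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    origin: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3 or grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("grid values must be 0 or 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "grid", grid.astype(np.uint8, copy=False))
        object.__setattr__(
            self, "origin", np.asarray(self.origin, dtype=float).reshape(3)
        )

    @property
    def shape(self) -> tuple:
        return self.grid.shape


@dataclasses.dataclass(frozen=True)
class Centerline:
    """Ordered 3D polyline in mm; ``arc_lengths`` is cumulative chord length."""

    xyz: np.ndarray
    arc_lengths: np.ndarray = None

    def __post_init__(self):
        xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 2:
            raise InvalidCenterlineError("centerline must be an (n>=2, 3) array")
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "arc_lengths", arc)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])


# ---------------------------------------------------------------------------
# centerline text I/O


def read_reference(path, label: str = None) -> ReferenceCenterline:
    """Read an ``x y z r`` centerline text file (mm)."""
    path = Path(path)
    xyz, radii = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise CenterlineParseError(
                    path, lineno, f"expected at least 4 fields, got {len(fields)}"
                )
            try:
                vals = [float(v) for v in fields[:4]]
            except ValueError:
                raise CenterlineParseError(
                    path, lineno, f"non-numeric field in {fields[:4]!r}"
                ) from None
            xyz.append(vals[:3])
            radii.append(vals[3])
    if len(xyz) < 2:
        raise InvalidCenterlineError(f"{path}: fewer than 2 centerline points")
    return ReferenceCenterline(
        np.array(xyz), np.array(radii), label=label if label is not None else path.stem
    )


def write_reference(ref: ReferenceCenterline, path) -> None:
    with open(path, "w") as fh:
        for (x, y, z), r in zip(ref.xyz, ref.radii):
            fh.write(f"{x:.10g} {y:.10g} {z:.10g} {r:.10g}\n")


# ---------------------------------------------------------------------------
# NIfTI volume I/O


def _check_affine(affine: np.ndarray) -> tuple:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off) > 1e-6):
        raise UnsupportedOrientationError(
            "only axis-aligned NIfTI affines are supported"
        )
    scales = np.diag(rot)
    if np.any(scales <= 0):
        raise UnsupportedOrientationError(
            "negative or zero affine scales are not supported"
        )
    if np.ptp(scales) > 1e-6 * scales.mean():
        raise UnsupportedOrientationError(
            f"anisotropic voxels are not supported (scales {scales})"
        )
    return float(scales.mean()), affine[:3, 3].astype(float)


def read_volume(path) -> BinaryVolume:
    """Load a NIfTI volume, binarizing every non-zero value to 1."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    voxel_size, origin = _check_affine(img.affine)
    grid = (np.asanyarray(img.dataobj) != 0).astype(np.uint8)
    return BinaryVolume(grid, voxel_size, origin)


def write_volume(vol: BinaryVolume, path) -> None:
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.grid, affine), str(path))


# ---------------------------------------------------------------------------
# coordinate maps


def voxel_to_mm(index, vol: BinaryVolume) -> np.ndarray:
    """World position (mm) of one or more voxel indices (voxel centers)."""
    return vol.origin + np.asarray(index, dtype=float) * vol.voxel_size


def mm_to_voxel(q, vol: BinaryVolume) -> np.ndarray:
    """Nearest voxel index of a world position; ties round away from zero."""
    t = (np.asarray(q, dtype=float) - vol.origin) / vol.voxel_size
    idx = round_half_away(t).astype(int)
    shape = np.array(vol.shape)
    if np.any(idx < 0) or np.any(idx >= shape.reshape((1,) * (idx.ndim - 1) + (3,))):
        raise OutOfBoundsError(f"position {q} maps outside grid of shape {vol.shape}")
    return idx
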