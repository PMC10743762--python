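"""Stacked per-axis medial surfaces and their pairwise/triple intersections.

The 3D divide-and-conquer strategy: slice the binary volume perpendicular
to each coordinate axis, skeletonize every slice in 2D, stack the skeleton
points back into a voxelized *medial surface* per axis, then intersect the
three surfaces.  Points common to two slicing directions (XY, YZ, XZ) or to
all three (XYZ) concentrate on the tube's centerline.

Because skeleton points from different slicing directions are quantized
independently, intersection uses a Chebyshev-distance tolerance (default
1 voxel); at tolerance 0 it is an exact set intersection.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .slice_skeleton import DEFAULT_PRUNE_RATIO, Slice2D, voronoi_skeleton
from .vessel_io import BinaryVolume, round_half_away

__all__ = [
    "MedialSurface",
    "CommonPointSet",
    "medial_surface",
    "common_surface",
    "xyz_common",
    "variant_common",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_PAIR_VARIANT = {
    frozenset("xy"): "XY",
    frozenset("yz"): "YZ",
    frozenset("xz"): "XZ",
}


@dataclasses.dataclass(frozen=True)
class MedialSurface:
    """Voxelized per-slice skeleton points from one slicing axis."""

    voxels: np.ndarray
    axis: str

    def __post_init__(self):
        if self.axis not in _AXIS_INDEX:
            raise ValueError(f"axis must be one of x/y/z, got {self.axis!r}")
        vox = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        object.__setattr__(self, "voxels", vox)

    def __len__(self) -> int:
        return self.voxels.shape[0]


@dataclasses.dataclass(frozen=True)
class CommonPointSet:
    """Voxels shared (up to tolerance) by two or three medial surfaces."""

    voxels: np.ndarray
    variant: str

    def __post_init__(self):
        if self.variant not in ("XY", "YZ", "XZ", "XYZ"):
            raise ValueError(f"unknown variant {self.variant!r}")
        vox = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        object.__setattr__(self, "voxels", vox)

    def __len__(self) -> int:
        return self.voxels.shape[0]


def medial_surface(
    vol: BinaryVolume, axis: str, prune_ratio: float = DEFAULT_PRUNE_RATIO
) -> MedialSurface:
    """Skeletonize every slice perpendicular to ``axis`` and stack the points.

    Skeleton (u, v) coordinates are snapped to the nearest in-plane voxel
    (ties away from zero, as everywhere in this package) and tagged with
    their slice index; empty slices are skipped.
    """
    ax = _AXIS_INDEX[axis]
    plane_axes = tuple(i for i in range(3) if i != ax)
    stack = np.moveaxis(vol.grid, ax, 0)
    nonempty = np.flatnonzero(stack.any(axis=(1, 2)))

    rows = []
    for idx in nonempty:
        sk = voronoi_skeleton(Slice2D(stack[idx], axis, int(idx)), prune_ratio)
        if len(sk) == 0:
            continue
        uv = round_half_away(sk.points).astype(int)
        np.clip(uv[:, 0], 0, stack.shape[1] - 1, out=uv[:, 0])
        np.clip(uv[:, 1], 0, stack.shape[2] - 1, out=uv[:, 1])
        ijk = np.empty((uv.shape[0], 3), dtype=int)
        ijk[:, ax] = idx
        ijk[:, plane_axes[0]] = uv[:, 0]
        ijk[:, plane_axes[1]] = uv[:, 1]
        rows.append(ijk)
    if rows:
        voxels = np.unique(np.concatenate(rows), axis=0)
    else:
        voxels = np.empty((0, 3), dtype=int)
    return MedialSurface(voxels, axis)


def _within(query: np.ndarray, targets: np.ndarray, tol: int) -> np.ndarray:
    """Boolean mask: query voxels with Chebyshev distance <= tol to targets."""
    if query.shape[0] == 0 or targets.shape[0] == 0:
        return np.zeros(query.shape[0], dtype=bool)
    dist, _ = cKDTree(targets).query(query, p=np.inf)
    return dist <= tol + 1e-9


def common_surface(
    a: MedialSurface, b: MedialSurface, tol_voxels: int = 1
) -> CommonPointSet:
    """Voxels of either surface within ``tol_voxels`` (Chebyshev) of the other."""
    if a.axis == b.axis:
        raise ValueError("common_surface requires surfaces from different axes")
    if tol_voxels < 0:
        raise ValueError("tol_voxels must be >= 0")
    variant = _PAIR_VARIANT[frozenset((a.axis, b.axis))]
    sel = [a.voxels[_within(a.voxels, b.voxels, tol_voxels)],
           b.voxels[_within(b.voxels, a.voxels, tol_voxels)]]
    merged = np.concatenate(sel) if sel else np.empty((0, 3), dtype=int)
    if merged.shape[0]:
        merged = np.unique(merged, axis=0)
    return CommonPointSet(merged, variant)


def xyz_common(
    x_s: MedialSurface,
    y_s: MedialSurface,
    z_s: MedialSurface,
    tol_voxels: int = 1,
) -> CommonPointSet:
    """Voxels of any surface within tolerance of *both* other surfaces."""
    surfaces = {s.axis: s for s in (x_s, y_s, z_s)}
    if set(surfaces) != {"x", "y", "z"}:
        raise ValueError("xyz_common requires one surface per axis")
    if tol_voxels < 0:
        raise ValueError("tol_voxels must be >= 0")
    picks = []
    order = ("x", "y", "z")
    for ax in order:
        own = surfaces[ax].voxels
        mask = np.ones(own.shape[0], dtype=bool)
        for other in order:
            if other != ax:
                mask &= _within(own, surfaces[other].voxels, tol_voxels)
        picks.append(own[mask])
    merged = np.concatenate(picks)
    if merged.shape[0]:
        merged = np.unique(merged, axis=0)
    return CommonPointSet(merged, "XYZ")


def variant_common(surfaces: dict, variant: str, tol_voxels: int = 1) -> CommonPointSet:
    """Common point set for a named variant from per-axis surfaces.

    ``surfaces`` maps axis name -> MedialSurface; XY/YZ/XZ need their two
    axes, XYZ needs all three.
    """
    variant = variant.upper()
    if variant == "XYZ":
        return xyz_common(
            surfaces["x"], surfaces["y"], surfaces["z"], tol_voxels=tol_voxels
        )
    pair = {"XY": ("x", "y"), "YZ": ("y", "z"), "XZ": ("x", "z")}.get(variant)
    if pair is None:
        raise ValueError(f"unknown variant {variant!r}")
    return common_surface(surfaces[pair[0]], surfaces[pair[1]], tol_voxels=tol_voxels)
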