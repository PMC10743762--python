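"""Synthetic vessel phantoms: parametric centerlines and union-of-spheres volumes.

The generator emulates the four vessel classes of the classic coronary
tracking benchmark layout — right coronary artery (RCA), left anterior
descending (LAD), left circumflex (LCX) and a large side-branch — as single
smooth 3D branches with gently tapering radii.  A ground-truth centerline is
voxelized into a binary segmentation by seeding a solid ball of the
annotated radius at every (rounded) centerline point and taking the union.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import PhantomError, SizeLimitError
from .vessel_io import (
    BinaryVolume,
    ReferenceCenterline,
    round_half_away,
    write_reference,
    write_volume,
)

__all__ = [
    "VESSEL_CLASSES",
    "PhantomSpec",
    "simulate_centerline",
    "round_centerline",
    "voxelize_union_of_spheres",
    "benchmark_specs",
    "generate_benchmark_set",
]

VESSEL_CLASSES = ("RCA", "LAD", "LCX", "BRANCH")

#: Default voxel budget guarding against accidental huge allocations.
DEFAULT_VOXEL_BUDGET = int(5e8)

# Nominal per-class geometry (mm).  Lengths and radii are scaled-down but
# anatomically ordered: the RCA/LAD are the longest and widest branches, the
# side-branch the shortest.  Tortuosity amplitudes are kept well below the
# self-intersection limit (curvature radius > 2x the maximum tube radius).
_CLASS_PARAMS = {
    "RCA": dict(length=55.0, radius_start=2.8, radius_end=1.1, tortuosity=0.04),
    "LAD": dict(length=45.0, radius_start=2.4, radius_end=0.9, tortuosity=0.04),
    "LCX": dict(length=35.0, radius_start=2.0, radius_end=0.8, tortuosity=0.04),
    "BRANCH": dict(length=22.0, radius_start=1.6, radius_end=0.7, tortuosity=0.03),
}


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vessel branch."""

    vessel_class: str
    length: float
    radius_start: float
    radius_end: float
    tortuosity: float = 0.03
    sample_spacing: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValueError(f"unknown vessel class {self.vessel_class!r}")
        if not self.length > 0:
            raise ValueError("length must be positive")
        if not (self.radius_start > 0 and self.radius_end > 0):
            raise ValueError("radii must be positive")
        if not self.sample_spacing > 0:
            raise ValueError("sample_spacing must be positive")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be non-negative")


def _curvature(xyz: np.ndarray, ds: float) -> np.ndarray:
    """Pointwise curvature magnitude of a uniformly sampled curve."""
    d1 = np.gradient(xyz, ds, axis=0)
    d2 = np.gradient(d1, ds, axis=0)
    cross = np.cross(d1, d2)
    speed = np.linalg.norm(d1, axis=1)
    return np.linalg.norm(cross, axis=1) / np.maximum(speed**3, 1e-12)


def simulate_centerline(spec: PhantomSpec) -> ReferenceCenterline:
    """Generate a smooth 3D centerline of total length ``spec.length``.

    The curve runs predominantly along +x with transverse (y, z)
    perturbations built from three random-phase harmonics whose amplitudes
    scale with ``tortuosity * length``; ``tortuosity == 0`` degenerates to a
    straight segment along +x.  Deterministic for a fixed seed.  Radii taper
    linearly in arc length from ``radius_start`` to ``radius_end``.
    """
    L = spec.length
    n = int(round(L / spec.sample_spacing)) + 1
    s_targets = np.linspace(0.0, L, n)

    if spec.tortuosity == 0.0:
        xyz = np.zeros((n, 3))
        xyz[:, 0] = s_targets
    else:
        rng = np.random.default_rng(spec.seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(2, 3))
        dt = spec.sample_spacing / 5.0
        t = np.arange(0.0, L + dt, dt)
        k = np.arange(1, 4)
        amp = spec.tortuosity * L / k**2
        dense = np.empty((t.size, 3))
        dense[:, 0] = t
        for axis in (1, 2):
            waves = amp * np.sin(2.0 * np.pi * np.outer(t, k) / L + phases[axis - 1])
            dense[:, axis] = waves.sum(axis=1)
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        # reparametrize to uniform arc length and truncate at total length L
        xyz = np.column_stack(
            [np.interp(s_targets, arc, dense[:, c]) for c in range(3)]
        )

        max_r = max(spec.radius_start, spec.radius_end)
        kappa = _curvature(xyz, spec.sample_spacing)
        kappa_max = float(kappa.max())
        if kappa_max > 0 and 1.0 / kappa_max <= 2.0 * max_r:
            raise PhantomError(
                f"tube self-intersects: minimum curvature radius "
                f"{1.0 / kappa_max:.3f} mm <= 2 x max radius {2 * max_r:.3f} mm"
            )

    radii = spec.radius_start + (spec.radius_end - spec.radius_start) * s_targets / L
    label = f"{spec.vessel_class}-seed{spec.seed}"
    return ReferenceCenterline(xyz, radii, label=label)


def round_centerline(ref: ReferenceCenterline, decimals: int = 1) -> ReferenceCenterline:
    """Round coordinates and radii, collapsing consecutive duplicate points.

    Ties round away from zero (the package-wide convention), so 0.05 mm
    becomes 0.1 mm at one decimal.
    """
    scale = 10.0**decimals
    xyz = round_half_away(ref.xyz * scale) / scale
    radii = round_half_away(ref.radii * scale) / scale
    keep = np.concatenate([[True], np.any(np.diff(xyz, axis=0) != 0.0, axis=1)])
    return ReferenceCenterline(xyz[keep], radii[keep], label=ref.label)


def voxelize_union_of_spheres(
    ref: ReferenceCenterline,
    voxel_size: float = 0.1,
    margin: float = None,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
) -> BinaryVolume:
    """Binary volume of the union of solid balls around the centerline.

    A voxel is foreground iff its center lies within distance ``r_p``
    (closed inequality) of at least one centerline point ``p``.  The
    bounding box covers every ball plus ``margin`` and is snapped to the
    voxel lattice anchored at the world origin, so coordinates rounded to
    one decimal land exactly on voxel centers at the default 0.1 mm size.
    """
    h = float(voxel_size)
    xyz, radii = ref.xyz, ref.radii
    max_r = float(radii.max())
    if margin is None:
        margin = max_r
    if margin < max_r:
        raise ValueError(f"margin {margin} must be >= max radius {max_r}")

    mins = (xyz - radii[:, None]).min(axis=0) - margin
    maxs = (xyz + radii[:, None]).max(axis=0) + margin
    lo = np.floor(mins / h).astype(int)
    hi = np.ceil(maxs / h).astype(int)
    shape = hi - lo + 1
    n_voxels = int(np.prod(shape.astype(np.int64)))
    if n_voxels > voxel_budget:
        raise SizeLimitError(
            f"grid {tuple(shape)} = {n_voxels} voxels exceeds budget {voxel_budget}"
        )
    origin = lo * h

    grid = np.zeros(shape, dtype=np.uint8)
    # drop repeated points; the union makes them redundant
    _, uniq = np.unique(np.column_stack([xyz, radii]), axis=0, return_index=True)
    for p, r in zip(xyz[np.sort(uniq)], radii[np.sort(uniq)]):
        c = (p - origin) / h
        ci = round_half_away(c).astype(int)
        w = int(np.ceil(r / h)) + 1
        a = np.maximum(ci - w, 0)
        b = np.minimum(ci + w, shape - 1)
        ii = origin[0] + np.arange(a[0], b[0] + 1) * h - p[0]
        jj = origin[1] + np.arange(a[1], b[1] + 1) * h - p[1]
        kk = origin[2] + np.arange(a[2], b[2] + 1) * h - p[2]
        d2 = (
            ii[:, None, None] ** 2 + jj[None, :, None] ** 2 + kk[None, None, :] ** 2
        )
        sub = grid[a[0] : b[0] + 1, a[1] : b[1] + 1, a[2] : b[2] + 1]
        sub[d2 <= r * r] = 1
    return BinaryVolume(grid, h, origin)


# ---------------------------------------------------------------------------
# benchmark dataset generation


def _jittered_spec(master_seed: int, dataset: int, class_index: int) -> PhantomSpec:
    vessel_class = VESSEL_CLASSES[class_index]
    base = _CLASS_PARAMS[vessel_class]
    rng = np.random.default_rng(
        np.random.SeedSequence([master_seed, dataset, class_index])
    )
    length = float(np.clip(base["length"] * rng.uniform(0.9, 1.1), 20.0, 60.0))
    r0 = float(np.clip(base["radius_start"] * rng.uniform(0.9, 1.1), 0.5, 3.0))
    r1 = float(np.clip(base["radius_end"] * rng.uniform(0.9, 1.1), 0.5, 3.0))
    tort = float(base["tortuosity"] * rng.uniform(0.8, 1.2))
    seed = int(rng.integers(2**31))
    return PhantomSpec(
        vessel_class=vessel_class,
        length=length,
        radius_start=r0,
        radius_end=r1,
        tortuosity=tort,
        seed=seed,
    )


def benchmark_specs(n_datasets: int, seed: int = 0) -> list:
    """Per-vessel specs of the benchmark: ``n_datasets`` x 4 vessel classes.

    Per-vessel RNG streams are derived from ``(seed, dataset, class)`` so
    every vessel is independent and reproducible.  Returns a list of
    ``(dataset_index, PhantomSpec)`` in dataset-major order.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    return [
        (d, _jittered_spec(seed, d, ci))
        for d in range(n_datasets)
        for ci in range(len(VESSEL_CLASSES))
    ]


def generate_benchmark_set(
    n_datasets: int, out_dir, seed: int = 0, voxel_size: float = 0.1
) -> list:
    """Write volume/reference pairs for every benchmark vessel.

    Returns a list of ``(volume_path, reference_path)`` tuples; also writes
    ``manifest.tsv`` (one tab-separated pair per line) into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for dataset, spec in benchmark_specs(n_datasets, seed):
        ref = round_centerline(simulate_centerline(spec))
        vol = voxelize_union_of_spheres(ref, voxel_size=voxel_size)
        stem = f"dataset{dataset}_{spec.vessel_class}"
        vol_path = out_dir / f"{stem}.nii"
        ref_path = out_dir / f"{stem}.txt"
        write_volume(vol, vol_path)
        write_reference(ref, ref_path)
        pairs.append((vol_path, ref_path))
    with open(out_dir / "manifest.tsv", "w") as fh:
        for vol_path, ref_path in pairs:
            fh.write(f"{vol_path}\t{ref_path}\n")
    return pairs
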