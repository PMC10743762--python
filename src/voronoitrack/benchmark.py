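"""End-to-end extraction pipeline and benchmark harness.

Runs the full method on a set of phantom vessels — voxelize, slice, build
medial surfaces, intersect, order, resample — evaluates every extraction
against its ground-truth centerline, and aggregates per-vessel, per-class
and grand-average tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom
from .centerline_path import order_points, resample
from .errors import VoronoiTrackError
from .medial_fusion import medial_surface, variant_common
from .rcaaef_metrics import evaluate
from .vessel_io import BinaryVolume, Centerline, read_reference, read_volume

__all__ = [
    "BenchmarkConfig",
    "extract_centerline",
    "run_benchmark",
    "run_from_specs",
    "summarize",
]

logger = logging.getLogger(__name__)

VARIANTS = ("XY", "YZ", "XZ", "XYZ")

_VARIANT_AXES = {"XY": ("x", "y"), "YZ": ("y", "z"), "XZ": ("x", "z")}


@dataclasses.dataclass(frozen=True)
class BenchmarkConfig:
    """Knobs of the extraction + evaluation pipeline."""

    tol_voxels: int = 1
    prune_ratio: float = 0.2
    n_samples: int = 1000
    voxel_size: float = 0.1


def extract_centerline(
    vol: BinaryVolume,
    variant: str = "XYZ",
    tol_voxels: int = 1,
    prune_ratio: float = 0.2,
    n_samples: int = 1000,
) -> Centerline:
    """Extract one centerline variant (XY, YZ, XZ or XYZ) from a binary volume."""
    variant = variant.upper()
    if variant == "XYZ":
        axes = ("x", "y", "z")
    elif variant in _VARIANT_AXES:
        axes = _VARIANT_AXES[variant]
    else:
        raise ValueError(f"unknown variant {variant!r}")

    surfaces = {ax: medial_surface(vol, ax, prune_ratio=prune_ratio) for ax in axes}
    common = variant_common(surfaces, variant, tol_voxels=tol_voxels)
    line = order_points(common, vol, tol_voxels=tol_voxels)
    return resample(line, n_samples)


def _evaluate_vessel(vol, ref, dataset, vessel_class, variants, config):
    # the three medial surfaces are shared by all variants; build them once
    axes_needed = sorted(
        {ax for v in variants for ax in (("x", "y", "z") if v == "XYZ" else _VARIANT_AXES[v])}
    )
    surfaces = {
        ax: medial_surface(vol, ax, prune_ratio=config.prune_ratio)
        for ax in axes_needed
    }
    rows = []
    for variant in variants:
        t0 = time.perf_counter()
        row = {
            "dataset": dataset,
            "vessel": vessel_class,
            "variant": variant,
            "ov": np.nan,
            "of": np.nan,
            "ot": np.nan,
            "ai": np.nan,
            "error": "",
        }
        try:
            common = variant_common(surfaces, variant, tol_voxels=config.tol_voxels)
            line = resample(
                order_points(common, vol, tol_voxels=config.tol_voxels),
                config.n_samples,
            )
            report = evaluate(line, ref, n=config.n_samples)
            row.update(
                ov=report.ov,
                of=report.of,
                ot=np.nan if report.ot is None else report.ot,
                ai=np.nan if report.ai is None else report.ai,
            )
        except VoronoiTrackError as exc:
            row["error"] = str(exc)
        elapsed = time.perf_counter() - t0
        logger.info(
            "dataset %s vessel %s variant %s: OV=%.2f OF=%.2f OT=%.2f AI=%.3f "
            "(%.1f s)%s",
            dataset,
            vessel_class,
            variant,
            row["ov"],
            row["of"],
            row["ot"],
            row["ai"],
            elapsed,
            f" ERROR: {row['error']}" if row["error"] else "",
        )
        rows.append(row)
    return rows


def run_from_specs(
    specs,
    variants=VARIANTS,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> pd.DataFrame:
    """Run the pipeline on in-memory phantom specs: ``[(dataset, PhantomSpec)]``.

    Returns the per-vessel table (one row per vessel x variant); failed
    extractions are kept as rows with an ``error`` message and NaN metrics.
    """
    rows = []
    for dataset, spec in specs:
        ref = phantom.round_centerline(phantom.simulate_centerline(spec))
        vol = phantom.voxelize_union_of_spheres(ref, voxel_size=config.voxel_size)
        rows.extend(
            _evaluate_vessel(vol, ref, dataset, spec.vessel_class, variants, config)
        )
    return pd.DataFrame(rows)


def run_benchmark(
    manifest,
    variants=VARIANTS,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> pd.DataFrame:
    """Run the pipeline on a manifest of ``(volume_path, reference_path)`` pairs.

    ``manifest`` may be a path to a tab-separated manifest file or an
    iterable of path pairs.  Dataset/vessel identifiers are taken from the
    file stems (``dataset<d>_<CLASS>`` when written by the phantom module,
    otherwise the bare stem).
    """
    if isinstance(manifest, (str, Path)):
        pairs = []
        with open(manifest) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    vol_path, ref_path = line.split("\t")
                    pairs.append((vol_path, ref_path))
    else:
        pairs = list(manifest)

    rows = []
    for vol_path, ref_path in pairs:
        stem = Path(vol_path).stem
        if stem.startswith("dataset") and "_" in stem:
            dataset, vessel_class = stem.split("_", 1)
            dataset = dataset.removeprefix("dataset")
        else:
            dataset, vessel_class = stem, stem
        vol = read_volume(vol_path)
        ref = read_reference(ref_path)
        rows.extend(_evaluate_vessel(vol, ref, dataset, vessel_class, variants, config))
    return pd.DataFrame(rows)


def summarize(per_vessel: pd.DataFrame):
    """Per-class means (over datasets) and grand means per variant.

    Mirrors the usual benchmark report layout: one mean row per vessel
    class and variant, plus one grand-average row per variant.  NaN metrics
    from failed extractions propagate into the means.
    """
    metrics = ["ov", "of", "ot", "ai"]
    per_class = (
        per_vessel.groupby(["vessel", "variant"], sort=False)[metrics]
        .mean()
        .reset_index()
    )
    grand = per_vessel.groupby("variant", sort=False)[metrics].mean().reset_index()
    return per_class, grand
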