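"""Standardized coronary centerline tracking accuracy metrics.

Implements the four measures of the Rotterdam coronary tracking evaluation
framework between an extracted centerline and a radius-annotated reference:

* **OV** — total overlap: symmetric true-positive fraction, where an
  extracted point is a true positive (TPM) iff it lies within one local
  vessel radius of the reference, and a reference point is a true positive
  (TPR) iff an extracted point lies within its radius;
  ``OV = (TPM + TPR) / (TPM + TPR + FN + FP)``.
* **OF** — overlap until first error: fraction of the reference tracked
  before the first false negative, ignoring false negatives in the first
  5 mm of the reference.
* **OT** — overlap of the clinically relevant portion: OV restricted to the
  reference up to the most distal point with diameter > 1.5 mm
  (radius >= 0.75 mm).
* **AI** — average inside distance: mean Euclidean distance over the
  true-positive correspondences of both directions, in mm.

Both curves are arc-length resampled to ``n`` points (default 1000) before
classification; reference radii are interpolated alongside.  Correspondence
is nearest-neighbor in Euclidean distance, thresholded by the *reference*
sample's radius in both directions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .centerline_path import resample_polyline
from .vessel_io import Centerline, ReferenceCenterline

__all__ = [
    "MetricCounts",
    "ClassificationResult",
    "MetricReport",
    "classify",
    "ov",
    "of_score",
    "ot_score",
    "ai_score",
    "evaluate",
]

#: False negatives within this arc length from the reference start are
#: ignored by OF (the measure is otherwise overly strict at the ostium).
OF_SKIP_MM = 5.0

#: Minimum reference radius (mm) of the "clinically relevant" portion
#: evaluated by OT (diameter > 1.5 mm).
OT_MIN_RADIUS_MM = 0.75


@dataclasses.dataclass(frozen=True)
class MetricCounts:
    """True/false positive and negative counts for one metric scope."""

    tpm: int
    fp: int
    tpr: int
    fn: int
    scope: str = "OV"


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """Per-point labels and match distances from `classify`."""

    ext_xyz: np.ndarray  # (n, 3) resampled extracted points; empty if none
    ref_xyz: np.ndarray  # (n, 3) resampled reference points
    ref_radii: np.ndarray  # (n,) interpolated reference radii
    ref_arc: np.ndarray  # (n,) reference arc-length positions
    ext_is_tpm: np.ndarray  # (n,) bool
    ext_dist: np.ndarray  # (n,) distance to nearest reference sample
    ext_nearest_ref: np.ndarray  # (n,) int index of that sample
    ref_is_tpr: np.ndarray  # (n,) bool
    ref_dist: np.ndarray  # (n,) distance to nearest extracted point
    n: int

    def counts(self) -> MetricCounts:
        return MetricCounts(
            tpm=int(self.ext_is_tpm.sum()),
            fp=int(self.ext_is_tpm.size - self.ext_is_tpm.sum()),
            tpr=int(self.ref_is_tpr.sum()),
            fn=int(self.n - self.ref_is_tpr.sum()),
            scope="OV",
        )


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """OV/OF/OT in percent, AI in mm, and the underlying counts."""

    ov: float
    of: float
    ot: float  # None when no reference point reaches the OT radius
    ai: float  # None when there are no true-positive correspondences
    counts: dict
    n_samples: int


def classify(
    extracted: Centerline, reference: ReferenceCenterline, n: int = 1000
) -> ClassificationResult:
    """Resample both curves to ``n`` points and label them TPM/FP and TPR/FN.

    ``extracted`` may be None, representing a failed extraction: every
    reference point is then a false negative.
    """
    ref_xyz, ref_radii, ref_arc = resample_polyline(
        reference.xyz, n, values=reference.radii
    )
    if extracted is None:
        return ClassificationResult(
            ext_xyz=np.empty((0, 3)),
            ref_xyz=ref_xyz,
            ref_radii=ref_radii,
            ref_arc=ref_arc,
            ext_is_tpm=np.zeros(0, dtype=bool),
            ext_dist=np.empty(0),
            ext_nearest_ref=np.empty(0, dtype=int),
            ref_is_tpr=np.zeros(n, dtype=bool),
            ref_dist=np.full(n, np.inf),
            n=n,
        )

    ext_xyz, _, _ = resample_polyline(extracted.xyz, n)
    ref_tree = cKDTree(ref_xyz)
    ext_dist, ext_nearest = ref_tree.query(ext_xyz)
    ext_is_tpm = ext_dist <= ref_radii[ext_nearest]

    ext_tree = cKDTree(ext_xyz)
    ref_dist, _ = ext_tree.query(ref_xyz)
    ref_is_tpr = ref_dist <= ref_radii

    return ClassificationResult(
        ext_xyz=ext_xyz,
        ref_xyz=ref_xyz,
        ref_radii=ref_radii,
        ref_arc=ref_arc,
        ext_is_tpm=ext_is_tpm,
        ext_dist=ext_dist,
        ext_nearest_ref=ext_nearest,
        ref_is_tpr=ref_is_tpr,
        ref_dist=ref_dist,
        n=n,
    )


def ov(counts: MetricCounts) -> float:
    """Total overlap in percent; 0 when there are no points at all."""
    denom = counts.tpm + counts.tpr + counts.fn + counts.fp
    if denom == 0:
        return 0.0
    return 100.0 * (counts.tpm + counts.tpr) / denom


def of_score(result: ClassificationResult, skip_mm: float = OF_SKIP_MM) -> float:
    """Overlap until first error, in percent.

    The first error is the most proximal false-negative reference point at
    arc length > ``skip_mm``; the score is the fraction of reference points
    before it that are true positives.  When every false negative lies
    within the first ``skip_mm``, those points are forgiven and the score
    is 100 minus the fraction of false negatives beyond — i.e. 100%.
    """
    fn = ~result.ref_is_tpr
    beyond = fn & (result.ref_arc > skip_mm)
    if not beyond.any():
        forgiven = int((fn & (result.ref_arc <= skip_mm)).sum())
        return 100.0 * (int(result.ref_is_tpr.sum()) + forgiven) / result.n
    first_error = int(np.flatnonzero(beyond)[0])
    tpr_of = int(result.ref_is_tpr[:first_error].sum())
    return 100.0 * tpr_of / result.n


def ot_score(
    result: ClassificationResult, min_radius_mm: float = OT_MIN_RADIUS_MM
):
    """Overlap restricted to the clinically relevant proximal portion.

    Reference points are restricted to ``[start, m]`` where ``m`` is the
    most distal sample with radius >= ``min_radius_mm``; extracted points
    are restricted to those matched to that span.  Returns ``(percent,
    counts)``; percent is None when no sample reaches the radius threshold.
    """
    big = np.flatnonzero(result.ref_radii >= min_radius_mm)
    if big.size == 0:
        return None, MetricCounts(0, 0, 0, 0, scope="OT")
    m = int(big[-1])
    ref_sel = np.arange(result.n) <= m
    tpr = int(result.ref_is_tpr[ref_sel].sum())
    fn = int(ref_sel.sum() - tpr)
    ext_sel = result.ext_nearest_ref <= m
    tpm = int(result.ext_is_tpm[ext_sel].sum())
    fp = int(ext_sel.sum() - tpm)
    counts = MetricCounts(tpm=tpm, fp=fp, tpr=tpr, fn=fn, scope="OT")
    return ov(counts), counts


def ai_score(result: ClassificationResult):
    """Mean match distance (mm) over TPM and TPR correspondences; None if none."""
    d = np.concatenate(
        [result.ext_dist[result.ext_is_tpm], result.ref_dist[result.ref_is_tpr]]
    )
    if d.size == 0:
        return None
    return float(d.mean())


def evaluate(
    extracted: Centerline,
    reference: ReferenceCenterline,
    n: int = 1000,
    of_skip_mm: float = OF_SKIP_MM,
    ot_min_radius_mm: float = OT_MIN_RADIUS_MM,
) -> MetricReport:
    """Compute OV, OF, OT and AI between an extraction and its reference."""
    result = classify(extracted, reference, n=n)
    counts_ov = result.counts()
    ot_val, counts_ot = ot_score(result, ot_min_radius_mm)
    of_val = of_score(result, of_skip_mm)
    counts_of = MetricCounts(
        tpm=0,
        fp=0,
        tpr=int(round(of_val / 100.0 * result.n)),
        fn=result.n - int(round(of_val / 100.0 * result.n)),
        scope="OF",
    )
    return MetricReport(
        ov=ov(counts_ov),
        of=of_val,
        ot=ot_val,
        ai=ai_score(result),
        counts={"OV": counts_ov, "OF": counts_of, "OT": counts_ot},
        n_samples=n,
    )
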