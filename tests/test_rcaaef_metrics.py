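import numpy as np
import pytest

from voronoitrack.centerline_path import resample_polyline
from voronoitrack.rcaaef_metrics import (
    MetricCounts,
    ai_score,
    classify,
    evaluate,
    of_score,
    ot_score,
    ov,
)
from voronoitrack.vessel_io import Centerline, ReferenceCenterline


def straight_reference(length=50.0, radius=1.0, n=51):
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.linspace(0, length, n)
    return ReferenceCenterline(xyz, np.full(n, radius))


def brute_force_metrics(ext_xyz, ref_xyz, ref_radii, ref_arc, skip_mm=5.0,
                        min_radius=0.75):
    """Independent O(n^2) recount of OV/OF/OT/AI with explicit loops."""
    n_ext, n_ref = len(ext_xyz), len(ref_xyz)
    ext_label = np.zeros(n_ext, bool)
    ext_dist = np.zeros(n_ext)
    ext_near = np.zeros(n_ext, int)
    for i in range(n_ext):
        d = [float(np.linalg.norm(ext_xyz[i] - ref_xyz[j])) for j in range(n_ref)]
        j = int(np.argmin(d))
        ext_near[i], ext_dist[i] = j, d[j]
        ext_label[i] = d[j] <= ref_radii[j]
    ref_label = np.zeros(n_ref, bool)
    ref_dist = np.zeros(n_ref)
    for j in range(n_ref):
        d = min(float(np.linalg.norm(ext_xyz[i] - ref_xyz[j])) for i in range(n_ext))
        ref_dist[j] = d
        ref_label[j] = d <= ref_radii[j]

    tpm, fp = int(ext_label.sum()), int((~ext_label).sum())
    tpr, fn = int(ref_label.sum()), int((~ref_label).sum())
    ov_val = 100.0 * (tpm + tpr) / (tpm + tpr + fn + fp)

    first_error = None
    for j in range(n_ref):
        if not ref_label[j] and ref_arc[j] > skip_mm:
            first_error = j
            break
    if first_error is None:
        of_val = 100.0
    else:
        of_val = 100.0 * sum(ref_label[:first_error]) / n_ref

    big = [j for j in range(n_ref) if ref_radii[j] >= min_radius]
    if not big:
        ot_val = None
    else:
        m = big[-1]
        tpr_t = sum(ref_label[: m + 1])
        fn_t = (m + 1) - tpr_t
        sel = [i for i in range(n_ext) if ext_near[i] <= m]
        tpm_t = sum(ext_label[i] for i in sel)
        fp_t = len(sel) - tpm_t
        ot_val = 100.0 * (tpm_t + tpr_t) / (tpm_t + tpr_t + fn_t + fp_t)

    dists = list(ext_dist[ext_label]) + list(ref_dist[ref_label])
    ai_val = float(np.mean(dists)) if dists else None
    return ov_val, of_val, ot_val, ai_val


class TestIdentities:
    def test_identity_is_perfect(self):
        ref = straight_reference()
        report = evaluate(Centerline(ref.xyz), ref)
        assert report.ov == 100.0
        assert report.of == 100.0
        assert report.ot == 100.0
        assert report.ai == pytest.approx(0.0, abs=1e-12)
        c = report.counts["OV"]
        assert (c.tpm, c.tpr, c.fp, c.fn) == (1000, 1000, 0, 0)

    def test_far_parallel_extraction_scores_zero(self):
        ref = straight_reference()
        ext = Centerline(ref.xyz + [0.0, 5.0, 0.0])
        report = evaluate(ext, ref)
        assert report.ov == 0.0
        assert report.of == 0.0
        assert report.ai is None
        c = report.counts["OV"]
        assert (c.tpm, c.tpr, c.fp, c.fn) == (0, 0, 1000, 1000)

    def test_small_constant_offset_all_matched(self):
        ref = straight_reference()
        ext = Centerline(ref.xyz + [0.0, 0.5, 0.0])
        res = classify(ext, ref)
        assert res.ext_is_tpm.all() and res.ref_is_tpr.all()
        np.testing.assert_allclose(res.ext_dist, 0.5, atol=1e-9)
        assert ai_score(res) == pytest.approx(0.5, abs=1e-9)

    def test_empty_extraction_all_false_negative(self):
        ref = straight_reference()
        res = classify(None, ref)
        c = res.counts()
        assert (c.tpm, c.fp, c.tpr, c.fn) == (0, 0, 0, 1000)


class TestOv:
    def test_half_overlap_arithmetic(self):
        assert ov(MetricCounts(tpm=500, fp=500, tpr=500, fn=500)) == 50.0

    def test_zero_denominator(self):
        assert ov(MetricCounts(0, 0, 0, 0)) == 0.0


class TestOf:
    def test_no_false_negative_gives_100(self):
        ref = straight_reference()
        assert of_score(classify(Centerline(ref.xyz), ref)) == 100.0

    def test_errors_only_in_first_5mm_forgiven(self):
        # extraction identical except truncated before 4 mm: proximal FNs only
        ref = straight_reference()
        xyz, _, s = resample_polyline(ref.xyz, 1000)
        ext = Centerline(xyz[s >= 4.0])
        res = classify(ext, ref)
        fn_arcs = res.ref_arc[~res.ref_is_tpr]
        assert fn_arcs.size > 0 and fn_arcs.max() <= 5.0
        assert of_score(res) == 100.0

    def test_mid_vessel_error_truncates_score(self):
        # extraction = first half of the reference only
        ref = straight_reference()
        xyz, _, s = resample_polyline(ref.xyz, 1000)
        ext = Centerline(xyz[s <= 25.0])
        res = classify(ext, ref)
        # expected by index arithmetic: reference sample k sits at arc
        # 50k/999 and is matched while within 1 mm of the extraction tip
        tip = ext.xyz[-1, 0]
        arc = 50.0 * np.arange(1000) / 999.0
        expected_first_error = int(np.flatnonzero(arc > tip + 1.0)[0])
        assert of_score(res) == pytest.approx(100.0 * expected_first_error / 1000)


class TestOt:
    def test_taper_below_threshold_excludes_distal_errors(self):
        n = 51
        xyz = np.zeros((n, 3))
        xyz[:, 0] = np.linspace(0, 50, n)
        radii = np.linspace(1.5, 0.5, n)  # crosses 0.75 mm at s = 37.5
        ref = ReferenceCenterline(xyz, radii)
        ext_xyz, _, s = resample_polyline(ref.xyz, 1000)
        ext_xyz = ext_xyz.copy()
        ext_xyz[s > 40.0, 1] += 3.0  # errors confined beyond the cutoff
        res = classify(Centerline(ext_xyz), ref)
        ot_val, _ = ot_score(res)
        assert ot_val == 100.0
        assert ov(res.counts()) < 100.0

    def test_all_radii_below_threshold_not_applicable(self):
        ref = straight_reference(radius=0.5)
        res = classify(Centerline(ref.xyz), ref)
        ot_val, _ = ot_score(res)
        assert ot_val is None


class TestAi:
    def test_mixed_offsets_average(self):
        # two-segment extraction offset by 0.1 then 0.3 mm; AI is the mean
        # over both correspondence directions, computed independently below
        ref = straight_reference()
        ext_xyz, _, s = resample_polyline(ref.xyz, 1000)
        ext_xyz = ext_xyz.copy()
        ext_xyz[:, 1] = np.where(s < 25.0, 0.1, 0.3)
        res = classify(Centerline(ext_xyz), ref)
        expected = np.concatenate(
            [res.ext_dist[res.ext_is_tpm], res.ref_dist[res.ref_is_tpr]]
        ).mean()
        assert ai_score(res) == pytest.approx(expected)
        assert 0.1 < ai_score(res) < 0.3

    def test_bounded_by_mean_matched_radius(self):
        rng = np.random.default_rng(3)
        ref = straight_reference()
        ext_xyz, _, _ = resample_polyline(ref.xyz, 1000)
        ext = Centerline(ext_xyz + rng.normal(0, 0.4, ext_xyz.shape))
        res = classify(ext, ref)
        val = ai_score(res)
        matched_radii = np.concatenate(
            [res.ref_radii[res.ext_nearest_ref][res.ext_is_tpm],
             res.ref_radii[res.ref_is_tpr]]
        )
        assert val <= matched_radii.mean()


class TestAgainstBruteForce:
    @pytest.mark.parametrize("case", range(4))
    def test_matches_quadratic_recount(self, case):
        rng = np.random.default_rng(100 + case)
        n = 40
        t = np.linspace(0, 30, 12)
        base = np.column_stack([t, 3 * np.sin(t / 6), 2 * np.cos(t / 9)])
        radii = rng.uniform(0.5, 1.5, 12)
        ref = ReferenceCenterline(base, radii)
        ext = Centerline(base + rng.normal(0, 0.6, base.shape))
        res = classify(ext, ref, n=n)
        report = evaluate(ext, ref, n=n)
        exp_ov, exp_of, exp_ot, exp_ai = brute_force_metrics(
            res.ext_xyz, res.ref_xyz, res.ref_radii, res.ref_arc
        )
        assert report.ov == pytest.approx(exp_ov)
        assert report.of == pytest.approx(exp_of)
        if exp_ot is None:
            assert report.ot is None
        else:
            assert report.ot == pytest.approx(exp_ot)
        if exp_ai is None:
            assert report.ai is None
        else:
            assert report.ai == pytest.approx(exp_ai)


class TestInvariances:
    def _case(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 40, 20)
        base = np.column_stack([t, 2 * np.sin(t / 5), np.cos(t / 7)])
        ref = ReferenceCenterline(base, np.full(20, 1.0))
        ext = Centerline(base + rng.normal(0, 0.5, base.shape))
        return ext, ref

    def test_rigid_transform_invariance(self):
        ext, ref = self._case()
        before = evaluate(ext, ref, n=200)
        # rotation about z by 30 degrees plus translation
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        shift = np.array([5.0, -3.0, 2.0])
        ext2 = Centerline(ext.xyz @ rot.T + shift)
        ref2 = ReferenceCenterline(ref.xyz @ rot.T + shift, ref.radii)
        after = evaluate(ext2, ref2, n=200)
        assert after.ov == pytest.approx(before.ov)
        assert after.of == pytest.approx(before.of)
        assert after.ot == pytest.approx(before.ot)
        assert after.ai == pytest.approx(before.ai, abs=1e-9)

    def test_reversed_extraction_unchanged(self):
        ext, ref = self._case()
        fwd = evaluate(ext, ref, n=200)
        rev = evaluate(Centerline(ext.xyz[::-1]), ref, n=200)
        assert rev.ov == pytest.approx(fwd.ov)
        assert rev.of == pytest.approx(fwd.of)
        assert rev.ot == pytest.approx(fwd.ot)
        assert rev.ai == pytest.approx(fwd.ai, abs=1e-9)
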