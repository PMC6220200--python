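import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femurseg.core_io import LabelMask, ProbabilityMap
from femurseg.metrics import (ConfusionCounts, asd,
                              aggregate_mean_sd, aggregate_median_iqr,
                              confusion, curves, dsc, holm_adjust, msd,
                              optimal_threshold, precision, recall,
                              reports_to_frame, significance_code, specificity,
                              subject_report, surface_voxels, wilcoxon_holm)
from tests.conftest import nonempty_random_mask, random_mask_pair


def loop_confusion(pred, gt):
    tp = fp = fn = tn = 0
    for p, g in zip(pred.data.ravel(), gt.data.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_asd_msd(pred, gt):
    """O(N_S * N_G) all-pairs oracle for Eqs. over voxel centers."""
    s = surface_voxels(pred).points_mm
    g = surface_voxels(gt).points_mm
    d = np.sqrt(((s[:, None, :] - g[None, :, :]) ** 2).sum(-1))
    d_s = d.min(axis=1)
    d_g = d.min(axis=0)
    a = (d_s.sum() + d_g.sum()) / (len(s) + len(g))
    m = max(d_s.max(), d_g.max())
    return a, m


class TestConfusion:
    def test_perfect(self, rng):
        m = nonempty_random_mask(rng)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0 and c.tp == int(m.data.sum())

    def test_complement(self, rng):
        m = nonempty_random_mask(rng)
        inv = LabelMask(1 - m.data, m.spacing)
        c = confusion(inv, m)
        assert c.tp == 0 and c.tn == 0

    def test_loop_oracle(self, rng):
        for _ in range(20):
            pred, gt = random_mask_pair(rng)
            c = confusion(pred, gt)
            assert (c.tp, c.fp, c.fn, c.tn) == loop_confusion(pred, gt)
            assert c.total == pred.data.size

    def test_shape_mismatch(self, rng):
        a = nonempty_random_mask(rng, shape=(8, 8, 8))
        b = nonempty_random_mask(rng, shape=(8, 8, 4))
        with pytest.raises(ValueError):
            confusion(a, b)


class TestOverlapMetrics:
    def test_dsc_hand_value(self):
        assert dsc(ConfusionCounts(tp=3, fp=1, fn=2, tn=10)) == pytest.approx(6 / 9)

    def test_dsc_identical_and_disjoint(self, rng):
        m = nonempty_random_mask(rng)
        assert dsc(confusion(m, m)) == 1.0
        empty_overlap = LabelMask(np.zeros_like(m.data), m.spacing)
        empty_overlap.data[0, 0, 0] = 1 - m.data[0, 0, 0]
        if m.data[0, 0, 0] == 0:
            assert dsc(confusion(empty_overlap, m)) == 0.0

    def test_recall_hand_value(self):
        assert recall(ConfusionCounts(tp=3, fp=0, fn=1, tn=0)) == pytest.approx(0.75)

    def test_both_empty_dsc_convention(self):
        with pytest.warns(UserWarning):
            assert dsc(ConfusionCounts(0, 0, 0, 0)) == 1.0

    def test_undefined_flagged_as_nan(self):
        assert np.isnan(precision(ConfusionCounts(tp=0, fp=0, fn=3, tn=5)))

    def test_dsc_is_harmonic_mean_of_precision_recall(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = [int(x) for x in rng.integers(1, 100, size=4)]
            c = ConfusionCounts(tp, fp, fn, tn)
            p, r = precision(c), recall(c)
            assert dsc(c) == pytest.approx(2 * p * r / (p + r))

    def test_permutation_invariance(self, rng):
        pred, gt = random_mask_pair(rng)
        perm = rng.permutation(pred.data.size)
        pred2 = LabelMask(pred.data.ravel()[perm].reshape(pred.shape), pred.spacing)
        gt2 = LabelMask(gt.data.ravel()[perm].reshape(gt.shape), gt.spacing)
        a, b = confusion(pred, gt), confusion(pred2, gt2)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


class TestSurface:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[2, 2, 2] = 1
        s = surface_voxels(LabelMask(m, (1, 1, 1)))
        assert len(s) == 1 and tuple(s.coords[0]) == (2, 2, 2)

    def test_cube_surface_count(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[1:4, 1:4, 1:4] = 1
        assert len(surface_voxels(LabelMask(m, (1, 1, 1)))) == 26

    def test_grid_boundary_counts_as_background(self):
        m = np.ones((4, 4, 4), dtype=np.uint8)
        # the whole solid block is surface: every voxel touches the grid edge
        # except the interior 2x2x2... which here is none (all touch edges)
        assert len(surface_voxels(LabelMask(m, (1, 1, 1)))) == 64 - 8

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            surface_voxels(LabelMask(np.zeros((3, 3, 3), dtype=np.uint8), (1, 1, 1)))


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        m = nonempty_random_mask(rng)
        assert asd(m, m) == 0.0
        assert msd(m, m) == 0.0

    def test_two_voxels_hand_distance(self):
        a = np.zeros((8, 8, 4), dtype=np.uint8)
        b = np.zeros((8, 8, 4), dtype=np.uint8)
        a[2, 2, 1] = 1
        b[4, 2, 1] = 1  # 2 in-plane voxels apart, sx = 0.5 -> 1.0 mm
        spacing = (0.5, 1.0, 1.0)
        assert asd(LabelMask(a, spacing), LabelMask(b, spacing)) == pytest.approx(1.0)
        assert msd(LabelMask(a, spacing), LabelMask(b, spacing)) == pytest.approx(1.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(10):
            pred = nonempty_random_mask(rng, shape=(7, 7, 5), p=0.2,
                                        spacing=(0.7, 1.1, 2.0))
            gt = nonempty_random_mask(rng, shape=(7, 7, 5), p=0.2,
                                      spacing=(0.7, 1.1, 2.0))
            a_ref, m_ref = brute_force_asd_msd(pred, gt)
            assert asd(pred, gt) == pytest.approx(a_ref, abs=1e-9)
            assert msd(pred, gt) == pytest.approx(m_ref, abs=1e-9)

    def test_symmetry(self, rng):
        a = nonempty_random_mask(rng, shape=(6, 6, 6))
        b = nonempty_random_mask(rng, shape=(6, 6, 6))
        assert asd(a, b) == pytest.approx(asd(b, a))
        assert msd(a, b) == pytest.approx(msd(b, a))

    def test_msd_at_least_asd(self, rng):
        for _ in range(5):
            a = nonempty_random_mask(rng, shape=(6, 6, 6))
            b = nonempty_random_mask(rng, shape=(6, 6, 6))
            assert msd(a, b) >= asd(a, b) - 1e-12

    def test_spacing_scaling(self, rng):
        a = nonempty_random_mask(rng, shape=(6, 6, 6))
        b = nonempty_random_mask(rng, shape=(6, 6, 6))
        a3 = LabelMask(a.data, (3, 3, 3))
        b3 = LabelMask(b.data, (3, 3, 3))
        assert asd(a3, b3) == pytest.approx(3 * asd(a, b))
        assert msd(a3, b3) == pytest.approx(3 * msd(a, b))

    def test_empty_side_undefined(self, rng):
        m = nonempty_random_mask(rng)
        empty = LabelMask(np.zeros_like(m.data), m.spacing)
        assert np.isnan(asd(empty, m))


class TestCurves:
    def _as_maps(self, scores, labels, shape):
        p = ProbabilityMap(scores.reshape(shape), (1, 1, 1))
        g = LabelMask(labels.reshape(shape).astype(np.uint8), (1, 1, 1))
        return p, g

    def test_perfect_separation(self, rng):
        labels = (rng.random(4 * 4 * 4) < 0.4).astype(float)
        p, g = self._as_maps(labels.copy(), labels, (4, 4, 4))
        roc, prc = curves(p, g)
        assert roc.area == pytest.approx(1.0)
        assert prc.area == pytest.approx(1.0)

    def test_random_scores_auc_half(self, rng):
        n = 100_000
        shape = (50, 50, 40)
        labels = np.zeros(n)
        labels[:n // 2] = 1
        rng.shuffle(labels)
        scores = rng.random(n)
        p, g = self._as_maps(scores, labels, shape)
        roc, _ = curves(p, g)
        assert roc.area == pytest.approx(0.5, abs=0.01)

    def test_hand_stepped_ap(self):
        # 6 voxels, scores/labels worked through every threshold by hand:
        # scores desc: .9(1) .8(0) .7(1) .6(1) .5(0) .4(0); recalls 1/3,1/3,2/3,1,1,1
        # AP = (1/3)*1 + 0 + (1/3)*(2/3) + (1/3)*(3/4) + 0 + 0 = 0.8055...
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        labels = np.array([1, 0, 1, 1, 0, 0])
        p, g = self._as_maps(scores, labels, (1, 2, 3))
        _, prc = curves(p, g)
        expected = (1 / 3) * 1.0 + (1 / 3) * (2 / 3) + (1 / 3) * (3 / 4)
        assert prc.area == pytest.approx(expected)

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score
        scores = rng.random(500)
        labels = (rng.random(500) < 0.3).astype(int)
        p, g = self._as_maps(scores, labels, (5, 10, 10))
        roc, prc = curves(p, g)
        assert prc.area == pytest.approx(average_precision_score(labels, scores))
        assert roc.area == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < 0.5).astype(int)
        p1, g = self._as_maps(scores, labels, (2, 10, 10))
        p2, _ = self._as_maps(scores ** 3 * 0.9, labels, (2, 10, 10))
        roc1, prc1 = curves(p1, g)
        roc2, prc2 = curves(p2, g)
        assert roc1.area == pytest.approx(roc2.area)
        assert prc1.area == pytest.approx(prc2.area)

    def test_recall_monotone_in_threshold(self, rng):
        scores = rng.random(300)
        labels = (rng.random(300) < 0.4).astype(int)
        p, g = self._as_maps(scores, labels, (3, 10, 10))
        roc, _ = curves(p, g)
        # thresholds descending -> recall and FPR non-decreasing along the array
        assert np.all(np.diff(roc.recall) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_errors(self, rng):
        p = ProbabilityMap(rng.random((3, 3, 3)), (1, 1, 1))
        g = LabelMask(np.ones((3, 3, 3), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            curves(p, g)


class TestMeanCurves:
    def test_identical_folds_reproduce_single_curve_area(self, rng):
        from femurseg.metrics import mean_curves
        scores = rng.random(400)
        labels = (rng.random(400) < 0.4).astype(int)
        p = ProbabilityMap(scores.reshape(4, 10, 10), (1, 1, 1))
        g = LabelMask(labels.reshape(4, 10, 10).astype(np.uint8), (1, 1, 1))
        roc_one, prc_one = curves(p, g)
        roc_mean, prc_mean = mean_curves([p, p, p], [g, g, g])
        assert roc_mean.area == pytest.approx(roc_one.area, abs=5e-3)
        assert prc_mean.area == pytest.approx(prc_one.area)

    def test_prc_area_is_mean_of_fold_aps(self, rng):
        from femurseg.metrics import mean_curves
        folds = []
        for _ in range(3):
            scores = rng.random(300)
            labels = (rng.random(300) < 0.5).astype(int)
            p = ProbabilityMap(scores.reshape(3, 10, 10), (1, 1, 1))
            g = LabelMask(labels.reshape(3, 10, 10).astype(np.uint8), (1, 1, 1))
            folds.append((p, g))
        aps = [curves(p, g)[1].area for p, g in folds]
        _, prc_mean = mean_curves([p for p, _ in folds], [g for _, g in folds])
        assert prc_mean.area == pytest.approx(np.mean(aps))


class TestOptimalThreshold:
    def test_perfect_scores_reach_corner(self, rng):
        labels = (rng.random(64) < 0.5).astype(float)
        p = ProbabilityMap(labels.reshape(4, 4, 4) * 0.8 + 0.1, (1, 1, 1))
        g = LabelMask(labels.reshape(4, 4, 4).astype(np.uint8), (1, 1, 1))
        _, prc = curves(p, g)
        t = optimal_threshold(prc)
        i = np.flatnonzero(prc.thresholds == t)[0]
        assert prc.precision[i] == 1.0 and prc.recall[i] == 1.0

    def test_tie_prefers_lower_threshold(self):
        from femurseg.metrics import CurveResult
        prc = CurveResult(thresholds=np.array([0.8, 0.3]),
                          precision=np.array([1.0, 0.5]),
                          recall=np.array([0.5, 1.0]),
                          fpr=np.zeros(2), specificity=np.ones(2),
                          area=0.0, kind="prc")
        assert optimal_threshold(prc) == pytest.approx(0.3)

    def test_argmin_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            scores = rng.random(50)
            labels = (rng.random(50) < 0.5).astype(int)
            if labels.sum() in (0, 50):
                continue
            p = ProbabilityMap(scores.reshape(1, 5, 10), (1, 1, 1))
            g = LabelMask(labels.reshape(1, 5, 10).astype(np.uint8), (1, 1, 1))
            _, prc = curves(p, g)
            t = optimal_threshold(prc)
            d2 = (1 - prc.precision) ** 2 + (1 - prc.recall) ** 2
            best = min(range(len(d2)), key=lambda i: (d2[i], -i))
            assert t == pytest.approx(float(prc.thresholds[best]))


class TestWilcoxonHolm:
    def test_exact_p_n6_all_positive(self):
        from femurseg.metrics import _paired_wilcoxon
        a = np.array([0.95, 0.94, 0.93, 0.96, 0.97, 0.92])
        b = a - np.array([0.01, 0.02, 0.015, 0.012, 0.03, 0.025])
        assert _paired_wilcoxon(a, b) == pytest.approx(2 / 64)

    def test_sign_enumeration_oracle(self, rng):
        # exact two-sided p by enumerating all 2^n sign assignments
        from femurseg.metrics import _paired_wilcoxon
        d = rng.normal(0.01, 0.02, size=8)
        d = d[d != 0]
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        n = len(d)
        total = ranks.sum()
        ws = []
        for bits in range(2 ** n):
            w = sum(ranks[i] for i in range(n) if bits >> i & 1)
            ws.append(w)
        ws = np.array(ws)
        stat = min(w_obs, total - w_obs)
        p_exact = np.mean(np.minimum(ws, total - ws) <= stat + 1e-12)
        if len(np.unique(np.abs(d))) == len(d):
            assert _paired_wilcoxon(d + 1.0, np.ones_like(d)) == pytest.approx(p_exact)

    def test_self_comparison_p_one(self):
        with pytest.warns(UserWarning):
            from femurseg.metrics import _paired_wilcoxon
            a = np.linspace(0.9, 0.95, 8)
            assert _paired_wilcoxon(a, a) == 1.0

    def test_holm_hand_values(self):
        # 3 raw p-values worked by hand: sorted (.01, .02, .04) ->
        # adjusted (.03, .04, .04)
        raw = [0.02, 0.01, 0.04]
        adj = holm_adjust(raw)
        assert adj == pytest.approx([0.04, 0.03, 0.04])

    def test_codes(self):
        assert significance_code(0.2) == "ns"
        assert significance_code(0.04) == "*"
        assert significance_code(0.004) == "**"
        assert significance_code(0.0004) == "***"

    def test_matrix_shape_and_symmetry(self, rng):
        table = pd.DataFrame({
            "m1": rng.normal(0.95, 0.01, 10),
            "m2": rng.normal(0.94, 0.01, 10),
            "m3": rng.normal(0.90, 0.01, 10)})
        pmat, cmat = wilcoxon_holm(table)
        assert pmat.shape == (3, 3)
        np.testing.assert_allclose(pmat.values, pmat.values.T)
        assert (cmat.values == cmat.values.T).all()

    def test_too_few_subjects(self, rng):
        table = pd.DataFrame({"a": rng.random(4), "b": rng.random(4)})
        with pytest.raises(ValueError):
            wilcoxon_holm(table)


class TestReports:
    def test_perfect_prediction(self, rng):
        m = nonempty_random_mask(rng, shape=(6, 6, 6))
        p = ProbabilityMap(m.data.astype(np.float32), m.spacing)
        rep = subject_report(p, m, m)
        assert rep.dsc == 1.0 and rep.precision == 1.0 and rep.recall == 1.0
        assert rep.asd_mm == 0.0 and rep.msd_mm == 0.0

    def test_fields_match_individual_operations(self, rng):
        pred = nonempty_random_mask(rng, shape=(6, 6, 6))
        gt = nonempty_random_mask(rng, shape=(6, 6, 6))
        rep = subject_report(None, pred, gt)
        c = confusion(pred, gt)
        assert rep.dsc == dsc(c)
        assert rep.asd_mm == asd(pred, gt)
        assert rep.msd_mm == msd(pred, gt)

    def test_aggregation_hand_computed(self):
        frame = pd.DataFrame({"subject_id": ["a", "b", "c"],
                              "dsc": [0.9, 0.8, 1.0]})
        agg = aggregate_mean_sd(frame).set_index("metric")
        assert agg.loc["dsc", "mean"] == pytest.approx(0.9)
        assert agg.loc["dsc", "sd"] == pytest.approx(0.1)

    def test_median_iqr(self):
        med, iqr = aggregate_median_iqr([1.0, 2.0, 3.0, 4.0])
        assert med == pytest.approx(2.5)
        assert iqr == pytest.approx(1.5)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=1, max_value=99), st.integers(min_value=0, max_value=99),
       st.integers(min_value=0, max_value=99))
def test_dsc_bounds_property(tp, fp, fn):
    v = dsc(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=5))
    assert 0.0 <= v <= 1.0
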