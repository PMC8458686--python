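"""Pixel metrics, IoU matching, object F1, error taxonomy, analyses."""

import numpy as np
import pytest

from brightnuc.evaluation import (OBJECT_F1_THRESHOLDS, count_merges_splits,
                                  count_missed, density_correlation,
                                  iou_matrix, object_f1,
                                  object_property_match, object_report,
                                  pixel_metrics, size_decile_analysis)
from brightnuc.training import AUGMENT_OPS, augment
from conftest import random_label_pair


class TestPixelMetrics:
    def test_identity_is_perfect(self, rng):
        m = rng.random((10, 10)) > 0.5
        pm = pixel_metrics(m, m)
        assert pm.precision == pm.recall == pm.f1 == 1.0

    def test_three_by_three_hand_count(self):
        gt = np.zeros((3, 3), bool)
        gt[0, :2] = gt[1, :2] = True          # 4 foreground
        pred = gt.copy()
        pred[1, 1] = False                     # one miss (3 overlap)
        pred[2, 2] = True                      # one false positive
        pm = pixel_metrics(pred, gt)
        assert (pm.tp, pm.fp, pm.fn, pm.tn) == (3, 1, 1, 4)
        assert pm.f1 == pytest.approx(6 / 8)
        assert pm.balanced_accuracy == pytest.approx((0.75 + 0.8) / 2)

    def test_empty_prediction_zero_f1(self):
        gt = np.ones((4, 4), bool)
        assert pixel_metrics(np.zeros((4, 4), bool), gt).f1 == 0.0

    def test_empty_vs_empty_is_one(self):
        assert pixel_metrics(np.zeros((4, 4), bool),
                             np.zeros((4, 4), bool)).f1 == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_metrics(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


def brute_force_iou(gt, pred):
    """Per-pair pixel-set oracle for the joint-histogram implementation."""
    kg, kp = int(gt.max()), int(pred.max())
    out = np.zeros((kg, kp))
    for i in range(1, kg + 1):
        a = set(zip(*np.nonzero(gt == i)))
        for j in range(1, kp + 1):
            b = set(zip(*np.nonzero(pred == j)))
            inter = len(a & b)
            union = len(a | b)
            out[i - 1, j - 1] = inter / union if union else 0.0
    return out


class TestIoUMatrix:
    def test_identical_maps(self):
        lab = np.zeros((8, 8), int)
        lab[1:3, 1:3] = 1
        lab[5:7, 5:7] = 2
        mt = iou_matrix(lab, lab)
        assert np.allclose(mt.iou, np.eye(2))

    def test_disjoint_objects_zero(self):
        a = np.zeros((6, 6), int)
        b = np.zeros((6, 6), int)
        a[0:2, 0:2] = 1
        b[4:6, 4:6] = 1
        assert iou_matrix(a, b).iou.max() == 0.0

    def test_hand_counted_overlap(self):
        gt = np.zeros((5, 5), int)
        pred = np.zeros((5, 5), int)
        gt[1:3, 1:3] = 1                 # 4 px
        pred[1:4, 1:3] = 1               # 6 px, 3 shared... build exactly 3
        pred[2, 2] = 0                   # now 5 px sharing 3
        pred[0, 4] = 0
        # recount: shared = {(1,1),(1,2),(2,1)} = 3; union = 4+5-3 = 6
        mt = iou_matrix(gt, pred)
        assert mt.iou[0, 0] == pytest.approx(3 / 6)

    def test_agrees_with_pixel_set_oracle(self, rng):
        for _ in range(20):
            gt, pred = random_label_pair(rng)
            mt = iou_matrix(gt, pred)
            assert np.allclose(mt.iou, brute_force_iou(gt, pred))


class TestObjectF1:
    def test_detection_rule_thresholds(self):
        # two GT/pred strip pairs at IoU exactly 0.7 (inter 7, union 10)
        gt = np.zeros((8, 20), int)
        pred = np.zeros((8, 20), int)
        gt[0, 0:10] = 1
        pred[0, 0:7] = 1
        gt[4, 0:10] = 2
        pred[4, 0:7] = 2
        mt = iou_matrix(gt, pred)
        assert np.allclose(np.diag(mt.iou), 0.7)
        assert object_f1(mt, 0.5) == 1.0
        assert object_f1(mt, 0.75) == 0.0
        grid = [object_f1(mt, float(t)) for t in OBJECT_F1_THRESHOLDS]
        assert np.mean(grid) == pytest.approx(0.5)  # detected at 5 of 10

    def test_empty_prediction(self):
        gt = np.zeros((6, 6), int)
        gt[1:4, 1:4] = 1
        gt[5, 5] = 2
        mt = iou_matrix(gt, np.zeros((6, 6), int))
        assert object_f1(mt, 0.5) == 0.0

    def test_non_increasing_in_threshold(self, rng):
        for _ in range(20):
            gt, pred = random_label_pair(rng)
            mt = iou_matrix(gt, pred)
            vals = [object_f1(mt, float(t)) for t in OBJECT_F1_THRESHOLDS]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def brute_force_taxonomy(gt, pred, thr_ms=0.1, thr_miss=0.6):
    iou = brute_force_iou(gt, pred)
    kg, kp = iou.shape
    merges = sum(1 for j in range(kp) if (iou[:, j] >= thr_ms).sum() >= 2)
    splits = sum(1 for i in range(kg) if (iou[i] >= thr_ms).sum() >= 2)
    if kg == 0:
        missed = 0
    elif kp == 0:
        missed = kg
    else:
        missed = sum(1 for i in range(kg) if iou[i].max() < thr_miss)
    return merges, splits, missed


class TestErrorTaxonomy:
    def test_one_prediction_covering_two_nuclei_is_a_merge(self):
        gt = np.zeros((20, 30), int)
        gt[5:15, 2:12] = 1
        gt[5:15, 13:23] = 2
        pred = np.zeros((20, 30), int)
        pred[5:15, 2:23] = 1  # 10x21 covering both
        mt = iou_matrix(gt, pred)
        assert np.allclose(mt.iou, 100 / 210)
        assert count_merges_splits(mt) == (1, 0)

    def test_two_predictions_on_one_nucleus_is_a_split(self):
        gt = np.zeros((20, 30), int)
        gt[5:15, 2:23] = 1
        pred = np.zeros((20, 30), int)
        pred[5:15, 2:12] = 1
        pred[5:15, 13:23] = 2
        assert count_merges_splits(iou_matrix(gt, pred)) == (0, 1)

    def test_perfect_segmentation_clean(self, rng):
        gt, _ = random_label_pair(rng)
        mt = iou_matrix(gt, gt)
        assert count_merges_splits(mt) == (0, 0)
        assert count_missed(mt) == 0

    def test_missed_boundary_convention(self):
        gt = np.zeros((4, 20), int)
        pred = np.zeros((4, 20), int)
        gt[0, 0:10] = 1
        pred[0, 0:6] = 1   # IoU 6/10 = 0.6 -> detected (>= rule)
        gt[2, 0:20] = 2
        pred[2, 0:11] = 2  # IoU 11/20 = 0.55 -> missed
        mt = iou_matrix(gt, pred)
        assert count_missed(mt) == 1

    def test_empty_prediction_misses_all(self):
        gt = np.zeros((10, 10), int)
        gt[1:3, 1:3] = 1
        gt[5:8, 5:8] = 2
        assert count_missed(iou_matrix(gt, np.zeros((10, 10), int))) == 2

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(30):
            gt, pred = random_label_pair(rng)
            mt = iou_matrix(gt, pred)
            merges, splits = count_merges_splits(mt)
            missed = count_missed(mt)
            assert (merges, splits, missed) == brute_force_taxonomy(gt, pred)


def test_metrics_invariant_under_joint_orientation_transforms(rng):
    gt, pred = random_label_pair(rng)
    base_pm = pixel_metrics(pred > 0, gt > 0).f1
    base_of = object_report(gt, pred).f1_avg
    for op in AUGMENT_OPS:
        gt2, pred2 = augment(gt, pred, op)
        assert pixel_metrics(pred2 > 0, gt2 > 0).f1 == pytest.approx(base_pm)
        assert object_report(gt2, pred2).f1_avg == pytest.approx(base_of)


class TestObjectProperties:
    def test_square_solidity_one_and_perfect_match(self):
        lab = np.zeros((20, 20), int)
        lab[2:8, 2:8] = 1
        lab[12:18, 11:19] = 2
        t = object_property_match(lab, lab)
        assert len(t) == 2
        assert np.allclose(t["gt_solidity"], 1.0)
        assert np.array_equal(t["gt_area"], t["pred_area"])
        assert np.allclose(t["iou"], 1.0)

    def test_concave_object_solidity_below_one(self):
        lab = np.zeros((20, 20), int)
        lab[2:12, 2:5] = 1     # C shape
        lab[2:5, 2:12] = 1
        lab[9:12, 2:12] = 1
        t = object_property_match(lab, lab)
        assert t["gt_solidity"][0] < 1.0

    def test_unmatched_objects_excluded(self):
        gt = np.zeros((20, 20), int)
        gt[2:8, 2:8] = 1
        pred = np.zeros((20, 20), int)
        pred[12:18, 12:18] = 1  # no overlap
        assert len(object_property_match(gt, pred)) == 0


class TestDensityCorrelation:
    def test_perfect_negative_line(self):
        pairs = [(n, 1.0 - 0.001 * n) for n in (10, 20, 30, 40)]
        r, slope = density_correlation(pairs)
        assert r == pytest.approx(-1.0)
        assert slope == pytest.approx(-0.001)

    def test_constant_f1_undefined_r_zero_slope(self):
        r, slope = density_correlation([(10, 0.8), (20, 0.8), (30, 0.8)])
        assert np.isnan(r)
        assert slope == 0.0

    def test_matches_textbook_formula(self, rng):
        pairs = [(float(n), float(f)) for n, f in
                 zip(rng.integers(5, 500, 5), rng.random(5))]
        r, _ = density_correlation(pairs)
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        rx = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(rx)

    def test_needs_three_images(self):
        with pytest.raises(ValueError):
            density_correlation([(1, 0.5), (2, 0.6)])


class TestSizeDeciles:
    def test_constant_iou_flat(self, rng):
        objs = [(a, 0.7) for a in rng.integers(10, 500, 40)]
        assert set(size_decile_analysis(objs).values()) == {0.7}

    def test_monotone_construction_increasing(self):
        areas = np.arange(1, 101)
        objs = list(zip(areas, areas / 100.0))
        med = size_decile_analysis(objs)
        vals = [med[d] for d in range(1, 11)]
        assert vals == sorted(vals)

    def test_matches_sort_bin_oracle(self, rng):
        areas = rng.integers(5, 1000, 100).astype(float)
        ious = rng.random(100)
        got = size_decile_analysis(zip(areas, ious))
        edges = np.quantile(areas, np.linspace(0, 1, 11))
        for d in range(1, 11):
            sel = (areas >= edges[d - 1]) & (
                (areas <= edges[d]) if d == 10 else (areas < edges[d]))
            assert got[d] == pytest.approx(np.median(ious[sel]))
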