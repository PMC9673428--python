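"""Confusion-matrix and boundary-distance metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from scunet.metrics import (AbsentClassError, BoundarySet, asd,
                            aggregate_reports, confusion_matrix,
                            evaluate_pair, extract_boundary, hausdorff95,
                            overlap_metrics)


def set_based_metrics(pred, truth, k, include_background=True):
    """Independent per-class set-operation computation of the overlap means."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    ious, pas, precs, dices = [], [], [], []
    lo = 0 if include_background else 1
    for c in range(lo, k + 1):
        p = pred == c
        t = truth == c
        if not p.any() and not t.any():
            continue
        inter = (p & t).sum()
        union = (p | t).sum()
        ious.append(inter / union if union else 0.0)
        pas.append(inter / t.sum() if t.sum() else 0.0)
        precs.append(inter / p.sum() if p.sum() else 0.0)
        denom = p.sum() + t.sum()
        dices.append(2 * inter / denom if denom else 0.0)
    return (np.mean(ious), np.mean(pas), np.mean(precs), np.mean(dices),
            (pred == truth).mean())


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        m = np.random.default_rng(0).integers(0, 4, (10, 10))
        cm = confusion_matrix(m, m, 3)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.counts.trace() == 100

    def test_four_pixel_hand_tabulation(self):
        truth = np.array([[0, 1], [1, 2]])
        pred = np.array([[0, 1], [2, 2]])
        cm = confusion_matrix(pred, truth, 2)
        assert cm.counts[0, 0] == 1
        assert cm.counts[1, 1] == 1
        assert cm.counts[1, 2] == 1
        assert cm.counts[2, 2] == 1
        assert cm.total == 4

    def test_swapping_arguments_transposes(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, (8, 8))
        b = rng.integers(0, 3, (8, 8))
        np.testing.assert_array_equal(confusion_matrix(a, b, 2).counts,
                                      confusion_matrix(b, a, 2).counts.T)

    @settings(derandomize=True, max_examples=50)
    @given(arrays(np.int64, (6, 6), elements=st.integers(0, 3)),
           arrays(np.int64, (6, 6), elements=st.integers(0, 3)))
    def test_counts_partition_pixels(self, pred, truth):
        cm = confusion_matrix(pred, truth, 3)
        assert cm.total == 36
        assert cm.counts.min() >= 0
        # row sums are the truth class histogram
        np.testing.assert_array_equal(cm.counts.sum(axis=1),
                                      np.bincount(truth.ravel(), minlength=4))

    def test_shape_and_label_violations(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.zeros((2, 2)), np.zeros((3, 3)), 1)
        with pytest.raises(ValueError):
            confusion_matrix(np.full((2, 2), 5), np.zeros((2, 2)), 3)


class TestOverlapMetrics:
    def test_perfect_prediction_fixed_point(self):
        m = np.random.default_rng(2).integers(0, 4, (12, 12))
        rep = overlap_metrics(confusion_matrix(m, m, 3))
        for v in (rep.miou, rep.mpa, rep.mprecision, rep.mdice, rep.accuracy):
            assert v == pytest.approx(1.0)

    def test_hand_evaluated_two_by_two(self):
        truth = np.array([[0, 1], [1, 2]])
        pred = np.array([[0, 1], [2, 2]])
        rep = overlap_metrics(confusion_matrix(pred, truth, 2))
        assert rep.accuracy == pytest.approx(3 / 4)
        # classes 0,1,2: IoU 1, 1/2, 1/2
        assert rep.miou == pytest.approx(2 / 3)

    @pytest.mark.parametrize("include_background", [True, False])
    def test_matches_set_operation_oracle(self, include_background):
        """1,000 random 8x8 mask pairs, k=3: confusion-matrix metrics equal
        metrics computed by direct per-class set operations."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            truth = rng.integers(0, 4, (8, 8))
            pred = np.where(rng.random((8, 8)) < 0.6, truth,
                            rng.integers(0, 4, (8, 8)))
            rep = overlap_metrics(confusion_matrix(pred, truth, 3),
                                  include_background=include_background)
            miou, mpa, mprec, mdice, acc = set_based_metrics(
                pred, truth, 3, include_background)
            assert rep.miou == pytest.approx(miou)
            assert rep.mpa == pytest.approx(mpa)
            assert rep.mprecision == pytest.approx(mprec)
            assert rep.mdice == pytest.approx(mdice)
            assert rep.accuracy == pytest.approx(acc)

    def test_all_metrics_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            rep = overlap_metrics(confusion_matrix(
                rng.integers(0, 3, (6, 6)), rng.integers(0, 3, (6, 6)), 2))
            for v in rep.to_dict().values():
                if np.isfinite(v):
                    assert 0.0 <= v <= 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(confusion_matrix(np.zeros((0, 0)),
                                             np.zeros((0, 0)), 1))


class TestBoundaryExtraction:
    def test_single_pixel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 3] = 1
        b = extract_boundary(mask, 1)
        np.testing.assert_array_equal(b.points, [[2, 3]])

    def test_filled_square_gives_perimeter(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[2:6, 2:6] = 2
        b = extract_boundary(mask, 2)
        assert len(b) == 12                      # 4x4 square: 16 - 4 interior
        assert not any((r, c) == (3, 3) for r, c in b.points)

    def test_full_image_class_boundary_is_border(self):
        mask = np.ones((6, 7), dtype=int)
        b = extract_boundary(mask, 1)
        assert len(b) == 2 * 6 + 2 * 7 - 4

    def test_absent_class_signalled(self):
        with pytest.raises(AbsentClassError):
            extract_boundary(np.zeros((4, 4), dtype=int), 2)


def brute_force_directed(a, b):
    return np.array([min(np.hypot(ax - bx, ay - by) for by, bx in b)
                     for ay, ax in a])


class TestBoundaryDistances:
    def test_identical_sets_zero(self):
        pts = BoundarySet(np.array([[0, 0], [1, 2], [3, 3]]))
        assert hausdorff95(pts, pts) == 0.0
        assert asd(pts, pts) == 0.0

    def test_three_four_five_triangle(self):
        a = BoundarySet(np.array([[0, 0]]))
        b = BoundarySet(np.array([[3, 4]]))
        assert hausdorff95(a, b) == pytest.approx(5.0)
        assert hausdorff95(a, b, spacing=2.0) == pytest.approx(10.0)

    def test_asd_hand_value(self):
        seg = BoundarySet(np.array([[0, 0], [0, 2]]))
        gt = BoundarySet(np.array([[0, 0]]))
        assert asd(seg, gt) == pytest.approx(1.0)
        assert asd(gt, seg) == pytest.approx(0.0)    # asymmetric by definition

    def test_matches_all_pairs_oracle(self):
        """200 random point-set pairs (<= 50 points): KD-tree distances equal
        brute-force all-pairs minima for HD95, HD100 and ASD."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            na, nb = rng.integers(1, 51, size=2)
            a = BoundarySet(rng.integers(0, 40, (na, 2)))
            b = BoundarySet(rng.integers(0, 40, (nb, 2)))
            dab = brute_force_directed(a.points, b.points)
            dba = brute_force_directed(b.points, a.points)
            hd95 = max(np.percentile(dab, 95), np.percentile(dba, 95))
            hd = max(dab.max(), dba.max())
            assert hausdorff95(a, b) == pytest.approx(hd95)
            assert hausdorff95(a, b, percentile=100) == pytest.approx(hd)
            assert asd(a, b) == pytest.approx(dab.mean())

    def test_hd100_symmetric_asd_not(self):
        rng = np.random.default_rng(6)
        a = BoundarySet(rng.integers(0, 20, (30, 2)))
        b = BoundarySet(rng.integers(0, 20, (10, 2)))
        assert hausdorff95(a, b, percentile=100) == \
            hausdorff95(b, a, percentile=100)
        assert asd(a, b, symmetric=True) == asd(b, a, symmetric=True)

    def test_empty_side_named_in_error(self):
        pts = BoundarySet(np.array([[0, 0]]))
        empty = BoundarySet(np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError, match="second"):
            hausdorff95(pts, empty)
        with pytest.raises(ValueError, match="first"):
            asd(empty, pts)


class TestEvaluatePair:
    def test_self_evaluation_is_perfect(self):
        mask = np.zeros((16, 16), dtype=int)
        mask[4:8, 4:8] = 1
        mask[10:14, 2:6] = 3
        rep = evaluate_pair(mask, mask, 3)
        assert rep.mdice == pytest.approx(1.0)
        assert rep.hausdorff95 == 0.0
        assert rep.asd == 0.0

    def test_aggregation_is_mean_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        reps = [evaluate_pair(rng.integers(0, 3, (8, 8)),
                              rng.integers(0, 3, (8, 8)), 2)
                for _ in range(5)]
        agg = aggregate_reports(reps)
        assert agg.miou == pytest.approx(np.mean([r.miou for r in reps]))
        shuffled = aggregate_reports(list(reversed(reps)))
        assert agg.to_dict() == pytest.approx(shuffled.to_dict(), nan_ok=True)
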