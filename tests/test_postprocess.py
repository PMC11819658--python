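"""Thresholding, median filtering, map fusion and accuracy metrics."""

import numpy as np
import pytest

import hsifm as h
from hsifm.postprocess import ConfusionCounts


class TestThreshold:
    def test_basic_and_boundary(self):
        np.testing.assert_array_equal(
            h.threshold_probs(np.array([0.2, 0.7]), 0.5), [0, 1]
        )
        assert h.threshold_probs(np.array([0.5]), 0.5)[0] == 1  # p == t -> 1
        assert h.threshold_probs(np.array([0.1, 0.2]), 0.9).sum() == 0

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_outside_open_interval_rejected(self, t):
        with pytest.raises(ValueError):
            h.threshold_probs(np.array([0.5]), t)


class TestMedianFilter:
    def test_constant_map_is_fixed_point(self):
        m = np.ones((5, 5), dtype=np.uint8)
        np.testing.assert_array_equal(h.median_filter(m, 3), m)

    def test_isolated_positive_removed(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[3, 3] = 1
        assert h.median_filter(m, 3).sum() == 0

    def test_solid_block_center_survives(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 1
        assert h.median_filter(m, 3)[3, 3] == 1

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            h.median_filter(np.zeros((3, 3), dtype=np.uint8), 2)

    def test_never_adds_isolated_positives(self, rng):
        def isolated(m):
            pad = np.pad(m, 1)
            count = 0
            for r, c in zip(*np.nonzero(m)):
                if pad[r : r + 3, c : c + 3].sum() == 1:
                    count += 1
            return count

        for _ in range(10):
            m = (rng.random((12, 12)) < 0.2).astype(np.uint8)
            assert isolated(h.median_filter(m, 3)) <= isolated(m)


class TestFusion:
    def test_and_is_idempotent(self, rng):
        m = (rng.random((6, 6)) < 0.4).astype(np.uint8)
        np.testing.assert_array_equal(h.fuse_maps(m, m).map, m)

    def test_and_suppresses_single_channel_positives(self):
        a = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        b = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        np.testing.assert_array_equal(h.fuse_maps(a, b).map, [[1, 0], [0, 0]])
        np.testing.assert_array_equal(
            h.fuse_maps(a, b, rule="or").map, [[1, 1], [0, 1]]
        )

    def test_shape_mismatch_and_unknown_rule(self):
        a = np.zeros((2, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            h.fuse_maps(a, np.zeros((3, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            h.fuse_maps(a, a, rule="xor")


class TestMetrics:
    def test_perfect_prediction(self):
        truth = np.array([[1, 0], [0, 1]])
        rec = h.metrics(h.confusion(truth, truth))
        for attr in ("precision", "recall", "f1", "bacc", "acc"):
            assert getattr(rec, attr) == 1.0

    def test_hand_computed_counts(self):
        rec = h.metrics(ConfusionCounts(TP=8, FP=2, FN=2, TN=88))
        assert rec.precision == pytest.approx(0.8)
        assert rec.recall == pytest.approx(0.8)
        assert rec.f1 == pytest.approx(0.8)
        assert rec.bacc == pytest.approx(0.88889, abs=1e-5)
        assert rec.acc == pytest.approx(0.96)

    def test_degenerate_all_negative(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        with pytest.warns(UserWarning):
            rec = h.metrics(h.confusion(z, z))
        assert rec.acc == 1.0
        assert np.isnan(rec.precision)

    def test_permutation_invariance(self, rng):
        pred = (rng.random(100) < 0.3).astype(np.uint8).reshape(10, 10)
        truth = (rng.random(100) < 0.2).astype(np.uint8).reshape(10, 10)
        perm = rng.permutation(100)
        c1 = h.confusion(pred, truth)
        c2 = h.confusion(
            pred.ravel()[perm].reshape(10, 10), truth.ravel()[perm].reshape(10, 10)
        )
        assert (c1.TP, c1.FP, c1.FN, c1.TN) == (c2.TP, c2.FP, c2.FN, c2.TN)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            rec = h.metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            assert min(rec.precision, rec.recall) - 1e-12 <= rec.f1
            assert rec.f1 <= max(rec.precision, rec.recall) + 1e-12

    def test_eval_mask_restricts_counts(self):
        pred = np.array([[1, 1], [0, 0]])
        truth = np.array([[1, 0], [0, 0]])
        mask = np.array([[True, False], [True, True]])
        c = h.confusion(pred, truth, mask)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 0, 0, 2)
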