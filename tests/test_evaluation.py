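import numpy as np
import pytest

from nuclei3d import GroundTruthLayer, compute_metrics, jaccard, match_labels
from nuclei3d.evaluation import detection_metrics, match_detections, render_overlay


def _square(canvas_shape, top, left, size, value=1):
    arr = np.zeros(canvas_shape, dtype=np.int32)
    arr[top : top + size, left : left + size] = value
    return arr


class TestJaccard:
    def test_identical_masks(self):
        m = _square((10, 10), 2, 2, 4) > 0
        assert jaccard(m, m) == 1.0

    def test_shifted_square_exhaustive(self):
        a = _square((12, 12), 2, 2, 4) > 0
        b = _square((12, 12), 2, 4, 4) > 0
        # 4x4 squares shifted by 2: intersection 8, union 24
        assert jaccard(a, b) == pytest.approx(8 / 24)

    def test_symmetry_and_identity_on_random(self, rng):
        for _ in range(20):
            a = rng.random((15, 15)) > 0.6
            b = rng.random((15, 15)) > 0.6
            assert jaccard(a, b) == jaccard(b, a)
            inter = np.count_nonzero(a & b)
            union = np.count_nonzero(a | b)
            expect = 1.0 if union == 0 else inter / union
            assert jaccard(a, b) == pytest.approx(expect)
            if union and not np.array_equal(a, b):
                assert jaccard(a, b) < 1.0


class TestMatching:
    def test_perfect_segmentation(self):
        gt = np.zeros((40, 40), dtype=np.int32)
        alg = np.zeros((40, 40), dtype=np.int32)
        for i in range(4):
            gt[i * 10 + 1 : i * 10 + 8, 5:12] = i + 1
            alg[i * 10 + 1 : i * 10 + 8, 5:12] = 9 - i
        m = match_labels(alg, gt)
        rep = compute_metrics(m)
        assert (rep.tp, rep.fp, rep.fn) == (4, 0, 0)
        assert rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.ji_avg == 1.0

    def test_split_nucleus_counts_fn_and_fp(self):
        gt = _square((20, 20), 4, 4, 10)  # area 100
        alg = np.zeros((20, 20), dtype=np.int32)
        alg[4:14, 4:9] = 1  # covers 50 (not > 50%)
        alg[4:14, 9:14] = 2  # covers 50
        rep = compute_metrics(match_labels(alg, gt))
        assert rep.fn == 1 and rep.tp == 0
        assert rep.fp == 2  # both split fragments are unnecessary divisions

    def test_under_segmentation_not_rechecked(self):
        # one big algorithm mask covering two expert nuclei
        gt = np.zeros((20, 30), dtype=np.int32)
        gt[5:15, 2:12] = 1
        gt[5:15, 14:24] = 2
        alg = np.zeros((20, 30), dtype=np.int32)
        alg[4:16, 1:25] = 1
        m = match_labels(alg, gt)
        rep = compute_metrics(m)
        assert rep.tp == 1 and rep.fn == 1 and rep.fp == 0
        cats = sorted(e.category for e in m.entries)
        assert cats == ["TP", "under-segmented"]

    def test_coverage_relative_to_expert_mask(self):
        gt = _square((20, 20), 5, 5, 8)  # area 64
        alg = np.zeros((20, 20), dtype=np.int32)
        alg[5:13, 5:9] = 1  # covers exactly 32 = 50%, not > 50%
        assert compute_metrics(match_labels(alg, gt)).tp == 0
        alg[5:13, 9] = 1  # now 40 > 50%
        assert compute_metrics(match_labels(alg, gt)).tp == 1

    def test_no_detections_all_fn(self):
        gt = _square((10, 10), 1, 1, 5)
        rep = compute_metrics(match_labels(np.zeros_like(gt), gt))
        assert rep.fn == 1 and rep.tp == 0
        assert np.isnan(rep.ji_avg) and np.isnan(rep.precision)


class TestMetricsArithmetic:
    @pytest.mark.parametrize(
        "tp,fp,fn,precision,recall",
        [(77, 1, 8, 0.987, 0.905), (88, 3, 6, 0.967, 0.936)],
    )
    def test_counts_to_rates(self, tp, fp, fn, precision, recall):
        p, r, _ = detection_metrics(tp, fp, fn)
        assert p == pytest.approx(precision, abs=1e-3)
        assert r == pytest.approx(recall, abs=1e-3)

    def test_matches_pixelwise_oracle_on_random_masks(self, rng):
        for _ in range(10):
            gt = np.zeros((30, 30), dtype=np.int32)
            alg = np.zeros((30, 30), dtype=np.int32)
            for i in range(3):
                t, l = rng.integers(0, 22, size=2)
                gt[t : t + 7, l : l + 7] = i + 1
                alg[t : t + 7, l : l + 7] = i + 1
            rep = compute_metrics(match_labels(alg, gt))
            for e in rep.per_nucleus:
                if e.jaccard is not None:
                    a = alg == e.alg_id
                    b = gt == e.gt_id
                    assert e.jaccard == pytest.approx(
                        np.count_nonzero(a & b) / np.count_nonzero(a | b)
                    )


class TestOverlay:
    def test_perfect_match_all_green(self):
        gt_arr = _square((16, 16), 2, 2, 6)
        layer = GroundTruthLayer(mask=gt_arr, layer_index=0)
        m = match_detections(gt_arr, layer)
        img = render_overlay(gt_arr, layer, m)
        assert (img[gt_arr > 0] == (0, 200, 0)).all()
        assert (img[gt_arr == 0] == 0).all()

    def test_empty_output_all_red(self):
        gt_arr = _square((16, 16), 2, 2, 6)
        layer = GroundTruthLayer(mask=gt_arr, layer_index=0)
        alg = np.zeros_like(gt_arr)
        img = render_overlay(alg, layer, match_detections(alg, layer))
        assert (img[gt_arr > 0] == (220, 0, 0)).all()

    def test_colour_counts_match_categories(self):
        gt = np.zeros((20, 40), dtype=np.int32)
        gt[2:10, 2:10] = 1    # will be TP
        gt[2:10, 20:28] = 2   # will be FN
        alg = np.zeros((20, 40), dtype=np.int32)
        alg[2:10, 2:10] = 1
        alg[12:18, 30:38] = 2  # FP
        layer = GroundTruthLayer(mask=gt, layer_index=0)
        m = match_detections(alg, layer)
        img = render_overlay(alg, layer, m)
        assert (img[gt == 1] == (0, 200, 0)).all()
        assert (img[gt == 2] == (220, 0, 0)).all()
        assert (img[alg == 2] == (40, 80, 255)).all()
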