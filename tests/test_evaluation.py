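import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shootcount import (
    Box,
    BoxAnnotation,
    count_metrics,
    iou,
    load_reference_tally,
    match_detections,
    pr_and_ap,
    split_dataset,
    tally_detections,
)
from shootcount.evaluation import DetectionMatchResult


def _boxes(image_id, specs, with_conf=False):
    bs = []
    for s in specs:
        conf = s[4] if with_conf else None
        bs.append(Box(s[0], s[1], s[2], s[3], confidence=conf))
    return BoxAnnotation(image_id, bs)


class TestIou:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_half_overlap_hand_computed(self):
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_disjoint(self):
        assert iou((0, 0, 5, 5), (6, 6, 9, 9)) == 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 5), (0, 0, 5, 5))


class TestMatchDetections:
    def test_perfect_predictions(self):
        gt = _boxes("i", [(0, 0, 10, 10, None), (20, 0, 30, 10, None), (0, 20, 10, 30, None)])
        pred = _boxes("i", [(0, 0, 10, 10, 0.9), (20, 0, 30, 10, 0.8), (0, 20, 10, 30, 0.7)], True)
        r = match_detections(pred, gt, 0.5)
        assert (r.tp, r.fp, r.fn) == (3, 0, 0)

    def test_duplicate_detection_counts_as_false(self):
        gt = _boxes("i", [(0, 0, 10, 10, None)])
        pred = _boxes("i", [(0, 0, 10, 10, 0.9), (1, 0, 11, 10, 0.8)], True)
        r = match_detections(pred, gt, 0.5)
        assert (r.tp, r.fp, r.fn) == (1, 1, 0)

    def test_no_predictions(self):
        gt = _boxes("i", [(0, 0, 5, 5, None)] * 1 + [(10, 0, 15, 5, None), (0, 10, 5, 15, None), (10, 10, 15, 15, None)])
        r = match_detections(BoxAnnotation("i", []), gt, 0.5)
        assert (r.tp, r.fp, r.fn) == (0, 0, 4)

    def test_tallies_partition_inputs(self):
        gt = _boxes("i", [(0, 0, 10, 10, None), (30, 30, 40, 40, None)])
        pred = _boxes("i", [(0, 0, 10, 10, 0.9), (50, 50, 60, 60, 0.3)], True)
        r = match_detections(pred, gt, 0.5)
        assert r.tp + r.fn == len(gt.boxes)
        assert r.tp + r.fp == len(pred.boxes)

    def test_confidence_required(self):
        gt = _boxes("i", [(0, 0, 10, 10, None)])
        with pytest.raises(ValueError):
            match_detections(gt, gt, 0.5)


class TestPRCurveAndAP:
    def test_hand_enumerated_sweep(self):
        # 2 GT; predictions: hit @0.9, miss @0.8, hit @0.7 -> AP = 5/6
        gt = [_boxes("i", [(0, 0, 10, 10, None), (20, 20, 30, 30, None)])]
        pred = [
            _boxes(
                "i",
                [(0, 0, 10, 10, 0.9), (50, 50, 60, 60, 0.8), (20, 20, 30, 30, 0.7)],
                True,
            )
        ]
        curve = pr_and_ap(pred, gt, 0.5)
        np.testing.assert_allclose(curve.recall, [0.5, 0.5, 1.0])
        np.testing.assert_allclose(curve.precision, [1.0, 0.5, 2 / 3])
        assert curve.ap == pytest.approx(5 / 6)

    def test_perfect_detector(self):
        gt = [_boxes("i", [(0, 0, 10, 10, None), (20, 20, 30, 30, None)])]
        pred = [_boxes("i", [(0, 0, 10, 10, 0.9), (20, 20, 30, 30, 0.8)], True)]
        assert pr_and_ap(pred, gt, 0.5).ap == pytest.approx(1.0)

    def test_always_wrong_detector(self):
        gt = [_boxes("i", [(0, 0, 10, 10, None)])]
        pred = [_boxes("i", [(50, 50, 60, 60, 0.9)], True)]
        assert pr_and_ap(pred, gt, 0.5).ap == 0.0

    def test_ap_invariant_to_monotone_confidence_rescaling(self):
        gt = [_boxes("i", [(0, 0, 10, 10, None), (20, 20, 30, 30, None)])]
        pred = [
            _boxes(
                "i",
                [(0, 0, 10, 10, 0.9), (50, 50, 60, 60, 0.8), (20, 20, 30, 30, 0.7)],
                True,
            )
        ]
        ap1 = pr_and_ap(pred, gt, 0.5).ap
        squashed = [
            BoxAnnotation(
                "i",
                [
                    Box(*b.as_tuple(), confidence=b.confidence**3)
                    for b in pred[0].boxes
                ],
            )
        ]
        assert pr_and_ap(squashed, gt, 0.5).ap == pytest.approx(ap1)

    def test_no_gt_rejected(self):
        with pytest.raises(ValueError):
            pr_and_ap([_boxes("i", [(0, 0, 1, 1, 0.5)], True)], [BoxAnnotation("i", [])], 0.5)


class TestTally:
    def test_column_sums(self):
        rows = [
            DetectionMatchResult("a", 3, 0, 0, [(0, 0, 1.0)] * 3),
            DetectionMatchResult("b", 2, 1, 1, [(0, 0, 0.9), (1, 1, 0.8)]),
        ]
        t = tally_detections(rows)
        assert (t["total"], t["correct"], t["false"], t["missed"]) == (6, 5, 1, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tally_detections([])

    def test_reference_tally_sums_match_published_totals(self):
        df = load_reference_tally()
        assert len(df) == 26
        assert int(df["total"].sum()) == 303
        assert int(df["yolox_correct"].sum()) == 296
        assert int(df["yolov5_correct"].sum()) == 277


class TestCountMetrics:
    def test_exact_predictions(self):
        m = count_metrics([3, 4], [3, 4])
        assert m.mae == 0.0 and m.mse == 0.0

    def test_hand_computed(self):
        m = count_metrics([5, 7], [4, 7])
        assert m.mae == pytest.approx(0.5)
        assert m.mse == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_and_jensen(self, seed):
        r = np.random.default_rng(seed)
        p, g = r.normal(10, 4, 17), r.normal(10, 4, 17)
        m = count_metrics(p, g)
        assert m.mae == pytest.approx(sum(abs(x - y) for x, y in zip(p, g)) / 17, abs=1e-12)
        assert m.mse == pytest.approx(sum((x - y) ** 2 for x, y in zip(p, g)) / 17, abs=1e-12)
        assert m.mae <= np.sqrt(m.mse) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_metrics([1.0], [1.0, 2.0])


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(1860, (1302, 279, 279)), (313, (219, 47, 47))],
    )
    def test_published_split_sizes(self, n, expected):
        tr, va, te = split_dataset(list(range(n)), (7, 1.5, 1.5), seed=0)
        assert (len(tr), len(va), len(te)) == expected

    @given(st.integers(3, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_exact_partition(self, n, seed):
        ids = list(range(n))
        tr, va, te = split_dataset(ids, (1, 1, 1), seed=seed)
        assert sorted(tr + va + te) == ids
        assert not (set(tr) & set(va)) and not (set(va) & set(te)) and not (set(tr) & set(te))

    def test_deterministic_given_seed(self):
        a = split_dataset(list(range(50)), seed=3)
        b = split_dataset(list(range(50)), seed=3)
        assert a == b

    def test_too_few_ids(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], (1, 1, 1))
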