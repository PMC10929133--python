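"""Losses, pixel metrics and report builders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rblkit.masks import RegionMap, ToothPositionStack
from rblkit.measurement import Stage
from rblkit.metrics import (
    ConfusionCounts,
    MetricError,
    confusion_counts,
    cross_entropy_loss,
    f1_from_precision_recall,
    f1_score,
    iou,
    multilabel_loss,
    pixel_accuracy,
    precision,
    segmentation_report,
    sensitivity,
    specificity,
    stage_report,
)

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
    fn=st.integers(0, 10_000), tn=st.integers(0, 10_000),
)


class TestConfusionCounts:
    def test_perfect_all_positive(self):
        ones = np.ones((6, 6), bool)
        c = confusion_counts(ones, ones)
        assert (c.tp, c.fp, c.fn, c.tn) == (36, 0, 0, 0)

    def test_all_false_positive(self):
        c = confusion_counts(np.ones((4, 4), bool), np.zeros((4, 4), bool))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 16, 0, 0)

    def test_matches_pixel_loop_oracle(self, rng):
        p = rng.random((8, 8)) > 0.5
        t = rng.random((8, 8)) > 0.5
        c = confusion_counts(p, t)
        tp = sum(p[i, j] and t[i, j] for i in range(8) for j in range(8))
        fp = sum(p[i, j] and not t[i, j] for i in range(8) for j in range(8))
        fn = sum(not p[i, j] and t[i, j] for i in range(8) for j in range(8))
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
        assert c.total == 64

    def test_shape_mismatch(self):
        with pytest.raises(MetricError):
            confusion_counts(np.ones((2, 2), bool), np.ones((3, 3), bool))


class TestPixelMetrics:
    def test_direct_substitution(self):
        c = ConfusionCounts(tp=1, fp=1, fn=1, tn=0)
        assert f1_score(c) == pytest.approx(0.5)
        assert iou(c) == pytest.approx(1 / 3)

    def test_perfect_prediction_all_ones(self):
        c = ConfusionCounts(tp=50, fp=0, fn=0, tn=50)
        for metric in (f1_score, iou, pixel_accuracy, sensitivity, specificity, precision):
            assert metric(c) == 1.0

    def test_zero_denominators_return_undefined_marker(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=5)
        assert f1_score(c) is None and iou(c) is None and sensitivity(c) is None
        assert specificity(c) == 1.0
        empty = ConfusionCounts(tp=0, fp=0, fn=0, tn=0)
        assert pixel_accuracy(empty) is None

    @settings(max_examples=200, derandomize=True)
    @given(counts_st)
    def test_f1_iou_identity(self, c):
        """F1 = 2*IoU/(1+IoU) for any single confusion matrix."""
        f1, j = f1_score(c), iou(c)
        if j is None:
            assert f1 is None
        else:
            assert abs(f1 - 2 * j / (1 + j)) < 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(counts_st)
    def test_metric_orderings(self, c):
        f1, j, pa = f1_score(c), iou(c), pixel_accuracy(c)
        if j is not None:
            assert j <= f1 <= 1
            if pa is not None:
                assert j <= pa + 1e-12


class TestF1FromPrecisionRecall:
    def test_harmonic_mean_of_equal_values_is_identity(self):
        for x in (0.25, 0.5, 0.93):
            assert f1_from_precision_recall(x, x) == pytest.approx(x)

    def test_reported_staging_rows(self):
        # printed per-stage precision/sensitivity pairs reproduce printed F1
        assert f1_from_precision_recall(0.7651, 0.6196) == pytest.approx(0.6847, abs=1e-4)
        assert f1_from_precision_recall(0.8149, 0.7752) == pytest.approx(0.7945, abs=1e-4)

    def test_both_zero_rejected(self):
        with pytest.raises(MetricError):
            f1_from_precision_recall(0.0, 0.0)


class TestLosses:
    def test_multilabel_half_probability_is_ln2(self, rng):
        y = (rng.random((5, 7, 3)) > 0.5).astype(float)
        p = np.full((5, 7, 3), 0.5)
        assert multilabel_loss(p, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_multilabel_perfect_prediction_near_zero(self, rng):
        y = (rng.random((4, 4, 2)) > 0.5).astype(float)
        assert multilabel_loss(y, y) <= 2e-7

    def test_multilabel_single_pixel_hand_value(self):
        # y=(1,0), p=(0.8,0.3): -(ln 0.8 + ln 0.7)/2
        y = np.array([[[1.0, 0.0]]])
        p = np.array([[[0.8, 0.3]]])
        assert multilabel_loss(p, y) == pytest.approx(-(np.log(0.8) + np.log(0.7)) / 2, abs=1e-9)
        assert multilabel_loss(p, y) == pytest.approx(0.28990, abs=1e-4)

    def test_cross_entropy_uniform_logits_is_ln4(self):
        z = np.zeros((3, 3, 4))
        y = np.zeros((3, 3, 4)); y[..., 2] = 1
        assert cross_entropy_loss(z, y) == pytest.approx(np.log(4), abs=1e-12)

    def test_cross_entropy_vanishes_with_large_margin(self):
        z = np.zeros((2, 2, 4)); y = np.zeros((2, 2, 4))
        z[..., 1] = 50.0; y[..., 1] = 1
        assert cross_entropy_loss(z, y) < 1e-20

    def test_cross_entropy_matches_per_pixel_oracle(self, rng):
        z = rng.normal(size=(3, 3, 4))
        labels = rng.integers(0, 4, size=(3, 3))
        y = np.eye(4)[labels]
        expected = 0.0
        for i in range(3):
            for j in range(3):
                e = np.exp(z[i, j])
                expected += -np.log(e[labels[i, j]] / e.sum())
        assert cross_entropy_loss(z, y) == pytest.approx(expected / 9, abs=1e-10)

    def test_losses_nonnegative_random(self, rng):
        y = (rng.random((6, 6, 3)) > 0.5).astype(float)
        p = rng.random((6, 6, 3))
        assert multilabel_loss(p, y) >= 0
        labels = rng.integers(0, 3, size=(6, 6))
        assert cross_entropy_loss(rng.normal(size=(6, 6, 3)), np.eye(3)[labels]) >= 0

    def test_label_without_class_rejected(self):
        z = np.zeros((1, 1, 4)); y = np.zeros((1, 1, 4))
        with pytest.raises(MetricError):
            cross_entropy_loss(z, y)


class TestSegmentationReport:
    def test_identical_inputs_score_one(self, rng):
        rm = RegionMap(labels=rng.integers(0, 4, size=(10, 10)))
        table = segmentation_report([rm], [rm])
        assert (table.loc[["intrabony", "suprabony", "crown"], ["iou", "f1"]] == 1.0).all().all()
        assert table.loc["macro", "iou"] == 1.0

    def test_absent_class_undefined_and_excluded_from_macro(self):
        labels = np.full((6, 6), 3, dtype=np.uint8)  # crown only
        rm = RegionMap(labels=labels)
        table = segmentation_report([rm], [rm])
        assert np.isnan(table.loc["intrabony", "iou"])
        assert table.loc["macro", "iou"] == 1.0  # crown alone defines the macro

    def test_duplicated_image_equals_single_image(self, rng):
        pred = RegionMap(labels=rng.integers(0, 4, size=(9, 9)))
        truth = RegionMap(labels=rng.integers(0, 4, size=(9, 9)))
        one = segmentation_report([pred], [truth])
        two = segmentation_report([pred, pred], [truth, truth])
        assert np.allclose(one["iou"].astype(float), two["iou"].astype(float), equal_nan=True)

    def test_position_stack_inputs(self, rng):
        masks = {3: rng.random((8, 8)) > 0.5, 4: rng.random((8, 8)) > 0.5}
        stack = ToothPositionStack(height=8, width=8, masks=masks)
        table = segmentation_report([stack], [stack])
        assert table.loc["pooled", "f1"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(MetricError):
            segmentation_report([], [])


class TestStageReport:
    def test_perfect_prediction(self):
        stages = [Stage.I] * 3 + [Stage.II] * 4 + [Stage.III] * 2
        table = stage_report(stages, stages)
        for name, support in (("Stage I", 3), ("Stage II", 4), ("Stage III", 2)):
            assert table.loc[name, "precision"] == 1.0
            assert table.loc[name, "sensitivity"] == 1.0
            assert table.loc[name, "support"] == support
        assert table.loc["Macro avg", "support"] == 9

    def test_macro_is_unweighted_mean_of_reported_rows(self):
        # printed per-stage precisions of the distance method -> printed macro
        vals = (0.7685, 0.7334, 0.8149)
        assert np.mean(vals) == pytest.approx(0.7722, abs=1e-4)

    def test_toy_confusion_matches_hand_computation(self):
        ref = [Stage.I] * 5 + [Stage.II] * 5 + [Stage.III] * 5
        pred = list(ref)
        pred[0] = Stage.II  # one stage-I tooth predicted as II
        table = stage_report(pred, ref)
        # Stage I one-vs-rest: TP=4, FN=1, FP=0, TN=10
        assert table.loc["Stage I", "precision"] == pytest.approx(1.0)
        assert table.loc["Stage I", "sensitivity"] == pytest.approx(4 / 5)
        assert table.loc["Stage I", "specificity"] == pytest.approx(1.0)
        # Stage II: TP=5, FP=1, FN=0, TN=9
        assert table.loc["Stage II", "precision"] == pytest.approx(5 / 6)
        assert table.loc["Stage II", "sensitivity"] == pytest.approx(1.0)
        assert table.loc["Stage II", "specificity"] == pytest.approx(9 / 10)
        assert table.loc["Macro avg", "precision"] == pytest.approx(
            np.mean([1.0, 5 / 6, 1.0]), abs=1e-12)
        assert int(table["support"][:3].sum()) == 15

    def test_supports_sum_and_macro_mean_property(self, rng):
        vals = [Stage.I, Stage.II, Stage.III]
        ref = [vals[i] for i in rng.integers(0, 3, size=60)]
        pred = [vals[i] for i in rng.integers(0, 3, size=60)]
        table = stage_report(pred, ref)
        assert int(table["support"][:3].sum()) == 60
        for col in ("precision", "sensitivity", "f1", "specificity"):
            stage_vals = table[col][:3].astype(float).dropna()
            assert table.loc["Macro avg", col] == pytest.approx(stage_vals.mean(), abs=1e-12)

    def test_length_mismatch_and_unknown_stage(self):
        with pytest.raises(MetricError):
            stage_report([Stage.I], [Stage.I, Stage.II])
        with pytest.raises(MetricError):
            stage_report(["I"], [Stage.I])
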