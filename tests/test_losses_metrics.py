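"""Label smoothing, smoothed losses, confusion counts and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bfpcnet as b
from bfpcnet.losses_metrics import metrics_report


# ---------------------------------------------------------------------------
# smoothing


def test_smoothing_values_at_default_rate():
    y = np.array([1, 0, 0, 0, 0, 0, 0, 0], float)
    ys = b.smooth_labels(y)
    assert np.isclose(ys[0], 0.9125)
    assert np.allclose(ys[1:], 0.0125)


def test_zero_rate_is_identity():
    y = np.array([0, 1, 1, 0, 0, 0, 1, 0], float)
    assert np.array_equal(b.smooth_labels(y, b.SmoothingParams(v=0.0)), y)


def test_one_hot_smoothed_labels_sum_to_one():
    y = np.zeros(8)
    y[3] = 1
    for v in (0.05, 0.1, 0.5):
        assert np.isclose(b.smooth_labels(y, b.SmoothingParams(v=v)).sum(), 1.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.integers(0, 1), min_size=8, max_size=8),
       st.floats(0.0, 0.99))
def test_smoothing_conserves_generalized_mass(bits, v):
    y = np.array(bits, float)
    ys = b.smooth_labels(y, b.SmoothingParams(v=v))
    assert np.isclose(ys.sum(), (1 - v) * y.sum() + v)


def test_invalid_rate_rejected():
    with pytest.raises(ValueError):
        b.smooth_labels(np.zeros(8), b.SmoothingParams(v=1.0))
    with pytest.raises(ValueError):
        b.smooth_labels(np.array([0, 2, 0, 0, 0, 0, 0, 0]))


# ---------------------------------------------------------------------------
# losses


def test_perfect_prediction_has_zero_loss():
    y = np.zeros(8)
    y[2] = 1
    y_hat = np.zeros(8)
    y_hat[2] = 1.0
    assert b.smoothed_loss(y, y_hat) == pytest.approx(0.0, abs=1e-6)


def test_uniform_prediction_loss_is_log_k():
    y = np.zeros(8)
    y[5] = 1
    ys = b.smooth_labels(y)                 # sums to 1
    loss = b.smoothed_loss(ys, np.full(8, 1 / 8))
    assert loss == pytest.approx(np.log(8), rel=1e-9)


def test_categorical_loss_matches_termwise_oracle():
    rng = np.random.default_rng(0)
    ys = rng.random(8)
    y_hat = rng.random(8) * 0.9 + 0.05
    expected = -sum(ys[k] * np.log(y_hat[k]) for k in range(8))
    assert b.smoothed_loss(ys, y_hat) == pytest.approx(expected, rel=1e-12)


def test_binary_loss_matches_termwise_oracle():
    rng = np.random.default_rng(1)
    ys = rng.random(8)
    y_hat = rng.random(8) * 0.9 + 0.05
    expected = -sum(ys[k] * np.log(y_hat[k]) + (1 - ys[k]) * np.log(1 - y_hat[k])
                    for k in range(8))
    assert b.smoothed_binary_loss(ys, y_hat) == pytest.approx(expected, rel=1e-12)


def test_loss_finite_on_hard_zero_predictions():
    y = np.ones(8)
    assert np.isfinite(b.smoothed_loss(y, np.zeros(8)))


def test_loss_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        b.smoothed_loss(np.zeros(8), np.zeros(7))


# ---------------------------------------------------------------------------
# confusion counts


def test_perfect_predictor_has_no_errors():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, (30, 8))
    counts = b.confusion(y, y.astype(float))
    assert (counts.fp == 0).all() and (counts.fn == 0).all()


def test_inverted_predictor_is_always_wrong():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, (30, 8))
    counts = b.confusion(y, 1.0 - y)
    assert (counts.tp == 0).all() and (counts.tn == 0).all()


def test_confusion_matches_double_loop_recount():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, (20, 8))
    probs = rng.random((20, 8))
    counts = b.confusion(y, probs, 0.5)
    for k in range(8):
        tp = fp = tn = fn = 0
        for i in range(20):
            pred = probs[i, k] >= 0.5
            if pred and y[i, k]:
                tp += 1
            elif pred and not y[i, k]:
                fp += 1
            elif not pred and not y[i, k]:
                tn += 1
            else:
                fn += 1
        assert (counts.tp[k], counts.fp[k], counts.tn[k], counts.fn[k]) == \
            (tp, fp, tn, fn)


def test_confusion_rejects_non_binary_truth():
    with pytest.raises(ValueError):
        b.confusion(np.full((3, 8), 2), np.zeros((3, 8)))


def test_count_invariant_totals():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, (17, 8))
    counts = b.confusion(y, rng.random((17, 8)))
    assert ((counts.tp + counts.fp + counts.tn + counts.fn) == 17).all()
    assert counts.n_samples == 17


# ---------------------------------------------------------------------------
# metrics


def test_perfect_counts_give_unit_metrics():
    counts = b.ConfusionCounts(tp=[3] * 8, fp=[0] * 8, tn=[5] * 8, fn=[0] * 8)
    for name, value in b.metrics(counts, "micro").items():
        assert value == 1.0


def test_hand_computed_metric_values():
    counts = b.ConfusionCounts(tp=[2], fp=[1], tn=[0], fn=[1])
    m = b.metrics(counts, "per_class")
    assert m["precision"][0] == pytest.approx(2 / 3)
    assert m["recall"][0] == pytest.approx(2 / 3)
    assert m["f1"][0] == pytest.approx(2 / 3)
    assert m["accuracy"][0] == pytest.approx(1 / 2)


def test_micro_equals_metrics_of_pooled_counts():
    rng = np.random.default_rng(4)
    tp, fp = rng.integers(0, 10, 8), rng.integers(0, 10, 8)
    base = rng.integers(0, 10, 8)
    total = (tp + fp + base).max() + rng.integers(1, 5)
    tn = total - tp - fp - base
    counts = b.ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=base)
    micro = b.metrics(counts, "micro")
    pooled = b.ConfusionCounts(tp=[tp.sum()], fp=[fp.sum()],
                               tn=[tn.sum()], fn=[base.sum()])
    per = b.metrics(pooled, "per_class")
    for k, v in micro.items():
        assert v == pytest.approx(per[k][0])


def test_zero_denominators_report_zero():
    counts = b.ConfusionCounts(tp=[0], fp=[0], tn=[5], fn=[0])
    m = b.metrics(counts, "per_class")
    assert m["precision"][0] == 0.0 and m["recall"][0] == 0.0


def test_unknown_averaging_rejected():
    counts = b.ConfusionCounts(tp=[1], fp=[0], tn=[0], fn=[0])
    with pytest.raises(ValueError):
        b.metrics(counts, "weighted")


def test_f1_is_harmonic_mean_of_precision_and_recall():
    rng = np.random.default_rng(5)
    for _ in range(50):
        tp, fp, fn = (int(v) for v in rng.integers(1, 20, 3))
        counts = b.ConfusionCounts(tp=[tp], fp=[fp], tn=[0], fn=[fn])
        m = b.metrics(counts, "per_class")
        p, r = m["precision"][0], m["recall"][0]
        assert m["f1"][0] == pytest.approx(2 * p * r / (p + r))


def test_metrics_agree_with_sklearn_reference():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(6)
    for _ in range(100):
        n = int(rng.integers(5, 40))
        y = rng.integers(0, 2, (n, 8))
        probs = rng.random((n, 8))
        counts = b.confusion(y, probs, 0.5)
        pred = (probs >= 0.5).astype(int)
        m = b.metrics(counts, "per_class")
        for k in range(8):
            assert m["precision"][k] == pytest.approx(sklearn_metrics.precision_score(
                y[:, k], pred[:, k], zero_division=0))
            assert m["recall"][k] == pytest.approx(sklearn_metrics.recall_score(
                y[:, k], pred[:, k], zero_division=0))
            assert m["f1"][k] == pytest.approx(sklearn_metrics.f1_score(
                y[:, k], pred[:, k], zero_division=0))
            assert m["accuracy"][k] == pytest.approx(sklearn_metrics.accuracy_score(
                y[:, k], pred[:, k]))


def test_report_table_layout():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, (12, 8))
    report = metrics_report(b.confusion(y, rng.random((12, 8))))
    assert list(report["class"]) == list(b.CLASSES) + ["micro", "macro"]
    assert {"TP", "FP", "TN", "FN", "accuracy", "precision", "recall",
            "f1"} <= set(report.columns)
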