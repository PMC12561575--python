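"""Early stopping, training determinism, and the evaluation statistics suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import blob_dataset, mini_model_config
from slenet.slenet_model import build_model
from slenet.train_eval import (
    CLASS_ORDER,
    ConfusionMatrix,
    EarlyStopper,
    MetricsReport,
    TrainConfig,
    ablation_grid,
    classification_metrics,
    confusion,
    evaluate_model,
    multi_seed_summary,
    paired_f1_tests,
    roc_pr_ovr,
    train_model,
)


class TestEarlyStopper:
    def test_stops_patience_epochs_after_peak(self):
        """Accuracy peaks at epoch 3 (1-based); patience 2 stops after epoch 5."""
        stopper = EarlyStopper(patience=2)
        values = [0.5, 0.6, 0.9, 0.7, 0.8]
        stops = [stopper.update(v, epoch) for epoch, v in enumerate(values, start=1)]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 3 and stopper.best == 0.9

    def test_monotone_improvement_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(v, i) for i, v in enumerate([0.1, 0.2, 0.3, 0.4]))

    def test_training_restores_best_epoch_weights(self):
        x, y = blob_dataset(n_per_class=3)
        data = {"train": (x, y), "val": (x[:8], y[:8])}
        net = build_model(mini_model_config(use_nonlocal=False), seed=0)
        cfg = TrainConfig(lr=1e-3, batch_size=8, max_epochs=4, patience=4, seed=0, augment=None)
        net, history = train_model(net, data, cfg)
        assert len(history["val_accuracy"]) <= 4
        assert history["best_epoch"] == int(np.argmax(history["val_accuracy"]))


class TestTraining:
    def test_overfits_a_tiny_separable_set(self):
        """A few epochs of the full recipe memorise 16 separable images."""
        x, y = blob_dataset(n_per_class=4)
        data = {"train": (x, y), "val": (x, y)}
        net = build_model(mini_model_config(), seed=0)
        cfg = TrainConfig(lr=3e-3, batch_size=8, max_epochs=25, patience=25, seed=0, augment=None)
        net, history = train_model(net, data, cfg)
        assert max(history["val_accuracy"]) == 1.0

    def test_same_seed_reproduces_history(self):
        x, y = blob_dataset(n_per_class=2)
        data = {"train": (x, y), "val": (x, y)}
        runs = []
        for _ in range(2):
            net = build_model(mini_model_config(use_nonlocal=False), seed=1)
            cfg = TrainConfig(lr=1e-3, batch_size=4, max_epochs=2, patience=2, seed=1)
            _, history = train_model(net, data, cfg)
            runs.append(history)
        assert runs[0] == runs[1]

    def test_empty_training_split_rejected(self):
        x, y = blob_dataset(n_per_class=1)
        net = build_model(mini_model_config(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_model(net, {"train": (x[:0], y[:0]), "val": (x, y)}, TrainConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(patience=200, max_epochs=100)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([0, 1, 2, 3], [0, 1, 2, 3])
        np.testing.assert_array_equal(cm.counts, np.eye(4, dtype=int))

    def test_direct_tally(self):
        cm = confusion(["E", "E", "M"], ["E", "M", "M"])
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1
        assert cm.total == 3

    def test_empty_inputs_give_zero_matrix(self):
        assert confusion([], []).counts.sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside class order"):
            confusion(["E"], ["X"])
        with pytest.raises(ValueError, match="outside class order"):
            confusion([0], [7])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix

        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        np.testing.assert_array_equal(
            confusion(y_true, y_pred).counts,
            confusion_matrix(y_true, y_pred, labels=range(4)),
        )


class TestClassificationMetrics:
    def test_diagonal_matrix_is_perfect(self):
        rep = classification_metrics(ConfusionMatrix(np.diag([5, 3, 2, 4])))
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())

    def test_binary_worked_example(self):
        """TP=50, FP=10, FN=10, TN=30: P = R = F1 = 0.8333, accuracy = 0.8."""
        cm = ConfusionMatrix(np.array([[50, 10], [10, 30]]), ("pos", "neg"))
        rep = classification_metrics(cm)
        assert rep.precision["pos"] == pytest.approx(0.8333, abs=1e-4)
        assert rep.recall["pos"] == pytest.approx(0.8333, abs=1e-4)
        assert rep.f1["pos"] == pytest.approx(0.8333, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.8)

    def test_absent_class_flagged_as_undefined(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 10
        rep = classification_metrics(ConfusionMatrix(counts))
        cls = CLASS_ORDER[1]
        assert rep.precision[cls] == 0.0 and rep.recall[cls] == 0.0
        assert "precision" in rep.undefined[cls]

    def test_macro_f1_bounded_by_class_f1(self, rng):
        counts = rng.integers(0, 30, (4, 4))
        rep = classification_metrics(ConfusionMatrix(counts))
        assert min(rep.f1.values()) <= rep.macro_f1 <= max(rep.f1.values())
        for d in (rep.precision, rep.recall, rep.f1):
            assert all(0.0 <= v <= 1.0 for v in d.values())

    def test_agrees_with_sklearn_macro_scores(self, rng):
        from sklearn.metrics import f1_score, precision_score, recall_score

        y_true = rng.integers(0, 4, 300)
        y_pred = rng.integers(0, 4, 300)
        rep = classification_metrics(confusion(y_true, y_pred))
        assert rep.macro_f1 == pytest.approx(f1_score(y_true, y_pred, average="macro"))
        assert rep.macro_precision == pytest.approx(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        )
        assert rep.macro_recall == pytest.approx(
            recall_score(y_true, y_pred, average="macro", zero_division=0)
        )


def mann_whitney_auc(pos_scores, neg_scores):
    """Pairwise-comparison oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestRocPr:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = roc_pr_ovr(y, scores, class_order=("a", "b"))
        assert out["auc"]["a"] == 1.0 and out["ap"]["b"] == 1.0

    def test_uninformative_scores_give_half_auc(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        scores = np.full((6, 2), 0.5)
        out = roc_pr_ovr(y, scores, class_order=("a", "b"))
        assert out["auc"]["a"] == pytest.approx(0.5)

    def test_matches_pairwise_comparison_oracle(self, rng):
        y = rng.integers(0, 3, 30)
        raw = rng.random((30, 3))
        scores = raw / raw.sum(axis=1, keepdims=True)
        out = roc_pr_ovr(y, scores, class_order=("a", "b", "c"))
        for i, cls in enumerate(("a", "b", "c")):
            expected = mann_whitney_auc(scores[y == i, i], scores[y != i, i])
            assert out["auc"][cls] == pytest.approx(expected, abs=1e-9)

    def test_six_sample_hand_set_scores(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        s1 = np.array([0.9, 0.8, 0.7, 0.45, 0.45, 0.1])
        scores = np.stack([1 - s1, s1], axis=1)
        out = roc_pr_ovr(y, scores, class_order=("neg", "pos"))
        expected = mann_whitney_auc(s1[y == 1], s1[y == 0])
        assert out["auc"]["pos"] == pytest.approx(expected)

    def test_degenerate_class_flagged(self):
        y = np.array([0, 0, 1, 1])
        scores = np.full((4, 3), 1 / 3)
        out = roc_pr_ovr(y, scores, class_order=("a", "b", "c"))
        assert "c" in out["degenerate"] and np.isnan(out["auc"]["c"])

    def test_unnormalised_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roc_pr_ovr(np.array([0, 1]), np.array([[2.0, 1.0], [1.0, 3.0]]))


def _report(f1_by_class, accuracy=0.9):
    macro = float(np.mean(list(f1_by_class.values())))
    return MetricsReport(
        accuracy=accuracy,
        precision=f1_by_class,
        recall=f1_by_class,
        f1=f1_by_class,
        macro_precision=macro,
        macro_recall=macro,
        macro_f1=macro,
    )


class TestMultiSeedSummary:
    def test_identical_runs_have_zero_interval(self):
        reports = [_report({c: 0.9 for c in CLASS_ORDER})] * 5
        summary = multi_seed_summary(reports)
        assert summary.ci_half_widths["macro_f1"] == pytest.approx(0.0, abs=1e-12)

    def test_five_value_student_t_interval(self):
        """Accuracies 90..98: mean 94, 95% CI half-width 2.776*sqrt(10)/sqrt(5)."""
        reports = [
            _report({c: 0.9 for c in CLASS_ORDER}, accuracy=a)
            for a in (90.0, 92.0, 94.0, 96.0, 98.0)
        ]
        summary = multi_seed_summary(reports)
        assert summary.means["accuracy"] == pytest.approx(94.0)
        assert summary.ci_half_widths["accuracy"] == pytest.approx(3.926, abs=1e-3)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            multi_seed_summary([_report({c: 0.9 for c in CLASS_ORDER})])

    def test_paired_tests_match_closed_form(self):
        a_vals = [0.90, 0.92, 0.91, 0.95, 0.93]
        b_vals = [0.88, 0.90, 0.90, 0.91, 0.90]
        reports_a = [_report({c: v for c in CLASS_ORDER}) for v in a_vals]
        reports_b = [_report({c: v for c in CLASS_ORDER}) for v in b_vals]
        out = paired_f1_tests(reports_a, reports_b)
        expected = stats.ttest_rel(a_vals, b_vals).pvalue
        d = np.array(a_vals) - np.array(b_vals)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        closed_form = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert out["per_class"]["E"] == pytest.approx(expected)
        assert out["per_class"]["E"] == pytest.approx(closed_form)
        assert out["average"] == pytest.approx(expected)

    def test_identical_paired_samples_flagged(self):
        reports = [_report({c: 0.9 for c in CLASS_ORDER}) for _ in range(5)]
        out = paired_f1_tests(reports, reports)
        assert out["per_class"]["E"] == 1.0 and set(out["degenerate"]) == set(CLASS_ORDER)


def test_evaluate_model_reports_curves(rng):
    x, y = blob_dataset(n_per_class=3)
    net = build_model(mini_model_config(use_nonlocal=False), seed=0)
    rep = evaluate_model(net, x, y)
    assert set(rep.auc) == set(CLASS_ORDER)
    assert 0.0 <= rep.accuracy <= 1.0


def test_ablation_grid_covers_all_four_variants():
    x, y = blob_dataset(n_per_class=2)
    data = {"train": (x, y), "val": (x, y), "test": (x, y)}
    cfg = mini_model_config()
    tc = TrainConfig(lr=1e-3, batch_size=4, max_epochs=1, patience=1, augment=None)
    table, reports = ablation_grid(data, cfg, tc, seeds=(0,))
    assert list(table["variant"]) == ["baseline", "+seca", "+nonlocal", "+seca+nonlocal"]
    assert table["macro_f1_mean"].notna().all()
    assert all(len(r) == 1 for r in reports.values())
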