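"""Labeling schemes, metric panel and cross-validation mechanics."""

import numpy as np
import pytest

import oracles
from gaitstab.evaluation import (compute_metrics, crossvalidate, make_labels)
from gaitstab.models import ModelSpec
from sklearn.metrics import matthews_corrcoef


def test_two_class_grouping_matches_stability_definition():
    mask, labels = make_labels(np.array(["NW", "COM", "STROOP", "MLP"]),
                               "two_class")
    assert mask.all()
    assert list(labels) == ["stable", "stable", "unstable", "unstable"]


def test_three_class_drops_perturbation_trials():
    mask, labels = make_labels(np.array(["NW", "MLP", "STROOP"]),
                               "three_class")
    assert list(labels) == ["NW", "STROOP"]
    with pytest.warns(RuntimeWarning, match="empty"):
        mask, labels = make_labels(np.array(["MLP", "MLP"]), "three_class")
    assert len(labels) == 0


def test_four_class_is_identity():
    conds = np.array(["NW", "STROOP", "COM", "MLP", "NW"])
    mask, labels = make_labels(conds, "four_class")
    assert mask.all() and np.array_equal(labels, conds)


def test_unknown_condition_rejected():
    with pytest.raises(ValueError, match="unknown condition"):
        make_labels(np.array(["NW", "RUNNING"]), "two_class")


def test_perfect_predictions_give_unit_metrics(rng):
    y = np.array(["a", "b", "a", "b", "a", "b"] * 5)
    scores = np.column_stack([(y == "a") * 1.0, (y == "b") * 1.0])
    m = compute_metrics(y, y, scores, np.array(["a", "b"]))
    for key in ("accuracy", "precision", "recall", "f_score", "mcc", "auc"):
        assert m[key] == pytest.approx(1.0)


def test_binary_mcc_closed_form():
    """Confusion TP=40 FN=10 FP=10 TN=40 -> accuracy 0.8, MCC 0.6."""
    y_true = np.array([1] * 50 + [0] * 50)
    y_pred = np.concatenate([np.ones(40), np.zeros(10),
                             np.ones(10), np.zeros(40)])
    m = compute_metrics(y_true, y_pred)
    assert m["accuracy"] == pytest.approx(0.8)
    assert m["mcc"] == pytest.approx(0.6)
    assert oracles.binary_mcc(40, 10, 10, 40) == pytest.approx(0.6)


def test_multiclass_mcc_reduces_to_binary(rng):
    y_true = rng.integers(0, 2, 200)
    y_pred = np.where(rng.random(200) < 0.8, y_true,
                      rng.integers(0, 2, 200))
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    assert matthews_corrcoef(y_true, y_pred) == pytest.approx(
        oracles.binary_mcc(tp, fn, fp, tn), abs=1e-12)


def test_binary_auc_equals_pair_counting(rng):
    y = rng.integers(0, 2, 40)
    y[:3] = [0, 1, 0]  # both classes present
    scores = rng.random(40)
    m = compute_metrics(y, y, np.column_stack([1 - scores, scores]),
                        np.array([0, 1]))
    assert m["auc"] == pytest.approx(
        oracles.auc_by_pair_counting(y, scores), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    s = rng.random(60)
    a1 = compute_metrics(y, y, np.column_stack([1 - s, s]),
                         np.array([0, 1]))["auc"]
    s2 = np.exp(5 * s)  # strictly monotone
    a2 = compute_metrics(y, y, np.column_stack([-s2, s2]),
                         np.array([0, 1]))["auc"]
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_absent_class_excluded_with_warning():
    y_true = np.array(["a", "a", "b", "b"])
    y_pred = np.array(["a", "b", "b", "b"])
    with pytest.warns(RuntimeWarning, match="absent"):
        m = compute_metrics(y_true, y_pred, None,
                            np.array(["a", "b", "c"]))
    assert 0 <= m["precision"] <= 1


def test_crossvalidation_tests_every_sample_once(rng):
    n = 100
    X = rng.standard_normal((n, 4))
    y = np.array(["a", "b"])[rng.integers(0, 2, n)]
    y[:10] = "a"
    spec = ModelSpec("random_forest", {"n_estimators": 20}, seed=0,
                     n_classes=2)
    rep = crossvalidate(X, y, spec, k=5, seed=0)
    assert sum(rep.fold_sizes) == n
    assert max(rep.fold_sizes) - min(rep.fold_sizes) <= 1
    conf = np.array(rep.confusion)
    assert conf.sum() == n
    # accuracy invariant: weighted fold average equals pooled confusion
    assert rep.metrics["accuracy"] == pytest.approx(
        np.trace(conf) / conf.sum())


def test_perfect_feature_gives_unit_cv_metrics(rng):
    n = 100
    y = np.array(["a", "b"])[rng.integers(0, 2, n)]
    X = np.column_stack([(y == "b") * 2.0 - 1.0])
    spec = ModelSpec("random_forest", {"n_estimators": 30}, seed=0,
                     n_classes=2)
    rep = crossvalidate(X, y, spec, k=5, seed=0)
    assert rep.metrics["accuracy"] == pytest.approx(1.0)
    assert rep.metrics["mcc"] == pytest.approx(1.0)


def test_random_features_give_chance_auc(rng):
    """Pure-noise features: AUC centred on 0.5 across seeds."""
    aucs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        n = 200
        X = r.standard_normal((n, 5))
        y = np.array(["a", "b"])[np.tile([0, 1], n // 2)]
        spec = ModelSpec("random_forest", {"n_estimators": 25}, seed=seed,
                         n_classes=2)
        rep = crossvalidate(X, y, spec, k=5, seed=seed)
        aucs.append(rep.metrics["auc"])
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_class_with_too_few_samples_rejected(rng):
    X = rng.standard_normal((10, 3))
    y = np.array(["a"] * 8 + ["b"] * 2)
    with pytest.raises(ValueError, match="fewer than"):
        crossvalidate(X, y, ModelSpec("random_forest", seed=0, n_classes=2),
                      k=5, seed=0)


def test_report_json_round_trip(rng):
    import json
    n = 60
    X = rng.standard_normal((n, 3))
    y = np.array(["a", "b"])[rng.integers(0, 2, n)]
    y[:6] = ["a", "b"] * 3
    spec = ModelSpec("random_forest", {"n_estimators": 10}, seed=0,
                     n_classes=2)
    rep = crossvalidate(X, y, spec, k=5, seed=0, labeling="two_class")
    parsed = json.loads(rep.to_json())
    assert parsed["labeling"] == "two_class"
    assert parsed["model_kind"] == "random_forest"
    assert set(parsed["metrics"]) >= {"accuracy", "precision", "recall",
                                      "f_score", "mcc", "roc_area", "auc"}


def test_subject_wise_folds_do_not_split_groups(rng):
    n = 200
    X = rng.standard_normal((n, 3))
    y = np.array(["a", "b"])[rng.integers(0, 2, n)]
    y[:20] = ["a", "b"] * 10
    groups = np.repeat(np.arange(10), 20)
    spec = ModelSpec("random_forest", {"n_estimators": 10}, seed=0,
                     n_classes=2)
    rep = crossvalidate(X, y, spec, k=5, seed=0, groups=groups)
    assert sum(rep.fold_sizes) == n
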