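"""Classifier contracts: architecture arithmetic, gradients, determinism,
chance-level behaviour and separable-data sanity."""

import numpy as np
import pytest

from gaitstab.models import (ChronoNetModel, ModelSpec, StackedLSTMModel,
                             build_chrononet, predict, train)
from gaitstab.nn import Tensor, ops
from gaitstab.evaluation import crossvalidate


def test_chrononet_temporal_lengths_ceil_mode():
    d = build_chrononet(64, 100, 4)
    assert d["block_output_lengths"] == [50, 25, 13]


def test_chrononet_block_width_is_concatenation():
    d = build_chrononet(64, 100, 4)
    assert all(b["out_channels"] == 96 for b in d["inception_blocks"])


def test_chrononet_dense_gru_input_widths():
    d = build_chrononet(64, 100, 4)
    assert [g["input_width"] for g in d["gru_layers"]] == [96, 32, 64, 96]


def test_chrononet_rejects_too_short_input():
    with pytest.raises(ValueError, match="stride-2"):
        build_chrononet(8, 4, 2)


def test_chrononet_description_is_json_serializable():
    import json
    json.dumps(build_chrononet(32, 100, 3))


def _finite_difference_check(model, X, y, n_params=6):
    logits = model.forward(Tensor(X), np.random.default_rng(0), False)
    loss = ops.softmax_cross_entropy(logits, y)
    loss.backward()
    params = model.params()
    step = max(1, len(params) // n_params)
    worst = 0.0
    for p in params[::step]:
        if p.grad is None:
            continue
        idx = np.unravel_index(np.argmax(np.abs(p.grad)), p.data.shape)
        orig = p.data[idx]
        eps = 1e-6
        for sign in (+1, -1):
            p.data[idx] = orig + sign * eps
            out = model.forward(Tensor(X), np.random.default_rng(0), False)
            val = float(ops.softmax_cross_entropy(out, y).data)
            if sign > 0:
                lp = val
            else:
                lm = val
        p.data[idx] = orig
        numeric = (lp - lm) / (2 * eps)
        worst = max(worst, abs(numeric - p.grad[idx]) / max(abs(numeric), 1e-8))
    return worst


def test_chrononet_gradients_match_finite_differences(rng):
    m = ChronoNetModel(3, 16, 2, seed=1, filters=4, kernels=(2, 4),
                       blocks=2, gru_layers=3, gru_units=4)
    X = rng.standard_normal((5, 3, 16))
    y = np.array([0, 1, 0, 1, 1])
    assert _finite_difference_check(m, X, y) < 1e-5


def test_lstm_gradients_match_finite_differences(rng):
    m = StackedLSTMModel(4, 3, seed=1, hidden=6, layers=2, dropout=0.0)
    X = rng.standard_normal((5, 12, 4))
    y = np.array([0, 1, 2, 1, 0])
    assert _finite_difference_check(m, X, y) < 1e-5


def _toy_data(rng, n=60):
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    Xf = np.column_stack([
        np.where(y == "a", -2.0, 2.0) + 0.1 * rng.standard_normal(n),
        rng.standard_normal(n)])
    Xt = np.zeros((n, 2, 100))
    Xt[:, 0, :] = Xf[:, 0, None]
    Xt[:, 1, :] = Xf[:, 1, None]
    return Xf, Xt, y


@pytest.mark.parametrize("kind", ["svm", "random_forest", "xgboost",
                                  "rnn_lstm", "chrononet"])
def test_separable_toy_set_reaches_perfect_training_accuracy(rng, kind):
    Xf, Xt, y = _toy_data(rng)
    hp = ({"epochs": 30, "patience": 30, "augment_shift": False}
          if kind in ("rnn_lstm", "chrononet") else {})
    spec = ModelSpec(kind, hp, seed=0, n_classes=2)
    X = Xt if spec.input_contract == "cycle_tensor" else Xf
    fitted = train(spec, X, y)
    labels, scores = predict(fitted, X)
    assert np.mean(labels == y) == 1.0
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)


def test_deep_training_loss_decreases_on_separable_data(rng):
    _, Xt, y = _toy_data(rng)
    spec = ModelSpec("chrononet", {"epochs": 12, "patience": 12,
                                   "augment_shift": False},
                     seed=0, n_classes=2)
    fitted = train(spec, Xt, y)
    losses = [h["train_loss"] for h in fitted.training_history]
    assert losses[-1] < losses[0]
    # non-increasing trend: no epoch rises above a small fraction of range
    span = losses[0] - min(losses)
    for a, b in zip(losses[:-1], losses[1:]):
        assert b <= a + 0.05 * span


def test_fixed_seed_gives_identical_predictions(rng):
    Xf, Xt, y = _toy_data(rng)
    for kind, X in (("random_forest", Xf), ("chrononet", Xt)):
        hp = {"epochs": 3, "patience": 3} if kind == "chrononet" else {}
        m1 = train(ModelSpec(kind, hp, seed=7, n_classes=2), X, y)
        m2 = train(ModelSpec(kind, hp, seed=7, n_classes=2), X, y)
        _, s1 = predict(m1, X)
        _, s2 = predict(m2, X)
        np.testing.assert_array_equal(s1, s2)


def test_contract_mismatch_raises(rng):
    Xf, Xt, y = _toy_data(rng)
    fitted = train(ModelSpec("random_forest", seed=0, n_classes=2), Xf, y)
    with pytest.raises(ValueError, match="2-D"):
        predict(fitted, Xt)
    with pytest.raises(ValueError, match="3-D"):
        train(ModelSpec("chrononet", {"epochs": 1}, seed=0, n_classes=2),
              Xf, y)


def test_single_class_labels_rejected(rng):
    Xf, _, _ = _toy_data(rng)
    with pytest.raises(ValueError, match="single class"):
        train(ModelSpec("svm", seed=0, n_classes=2), Xf,
              np.repeat("a", len(Xf)))


def test_unknown_kind_and_hyperparameters_rejected():
    with pytest.raises(ValueError, match="unknown model kind"):
        ModelSpec("mlp")
    with pytest.raises(ValueError, match="hyperparameters"):
        ModelSpec("svm", {"depth": 3})


def test_argmax_tie_break_is_lowest_index():
    scores = np.array([[0.1, 0.2, 0.7], [0.4, 0.4, 0.2]])
    assert np.argmax(scores[0]) == 2
    assert np.argmax(scores[1]) == 0  # tie -> lowest index


def test_label_permutation_gives_chance_level_cv(rng):
    """Random-forest CV accuracy on permuted 4-class labels is ~0.25."""
    accs = []
    for seed in range(5):
        r = np.random.default_rng(seed)
        n = 400
        X = r.standard_normal((n, 10))
        y = np.array(["a", "b", "c", "d"])[np.repeat(np.arange(4), n // 4)]
        y = r.permutation(y)
        spec = ModelSpec("random_forest", {"n_estimators": 100},
                         seed=seed, n_classes=4)
        rep = crossvalidate(X, y, spec, k=5, seed=seed)
        accs.append(rep.metrics["accuracy"])
    assert abs(np.mean(accs) - 0.25) < 0.05
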