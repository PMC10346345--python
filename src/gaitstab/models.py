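"""The five gait-stability classifiers.

Feature-based models (SVM with RBF kernel, random forest, gradient-boosted
trees) consume the selected cycle-level feature vectors; sequence models
(stacked LSTM, ChronoNet) consume the raw normalized cycle tensors
(channels x 100 per cycle).  ChronoNet stacks inception-style blocks of
three parallel 1-D convolutions with exponentially increasing kernel
lengths (2, 4, 8; 32 filters each, stride 2) followed by four GRU layers
whose inputs are densely connected in a feed-forward manner; the stacked
LSTM alternates LSTM(64) and dropout layers.

All training is deterministic under a fixed seed and sized for a single
CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import nn
from .nn import ops
from .io_formats import FeatureTable

__all__ = ["ModelSpec", "FittedModel", "build_chrononet", "train", "predict",
           "MODEL_KINDS"]

MODEL_KINDS = ("svm", "random_forest", "xgboost", "rnn_lstm", "chrononet")

_DEFAULT_HYPERS: dict[str, dict] = {
    "svm": {"C": 1.0, "gamma": "scale"},
    "random_forest": {"n_estimators": 500, "max_features": "sqrt"},
    "xgboost": {"n_estimators": 300, "max_depth": 4, "learning_rate": 0.1},
    "rnn_lstm": {"hidden": 64, "layers": 2, "dropout": 0.3, "epochs": 50,
                 "lr": 1e-3, "batch_size": 64, "patience": 10,
                 "augment_shift": True},
    "chrononet": {"filters": 32, "kernels": (2, 4, 8), "blocks": 3,
                  "gru_layers": 4, "gru_units": 32, "dropout": 0.0,
                  "epochs": 50, "lr": 2e-3, "batch_size": 64, "patience": 10,
                  "augment_shift": True},
}

DEEP_KINDS = ("rnn_lstm", "chrononet")


@dataclass
class ModelSpec:
    """Which classifier to train and with which hyperparameters."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; "
                             f"expected one of {MODEL_KINDS}")
        allowed = set(_DEFAULT_HYPERS[self.kind])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")
        if self.n_classes not in (2, 3, 4):
            raise ValueError("n_classes must be 2, 3 or 4")

    @property
    def hypers(self) -> dict:
        merged = dict(_DEFAULT_HYPERS[self.kind])
        merged.update(self.hyperparameters)
        return merged

    @property
    def input_contract(self) -> str:
        return "cycle_tensor" if self.kind in DEEP_KINDS else "features"


@dataclass
class FittedModel:
    spec: ModelSpec
    input_contract: str
    classes_: np.ndarray
    impl: object
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    training_history: list[dict] | None = None


def build_chrononet(n_channels: int, n_timesteps: int = 100,
                    n_classes: int = 2, filters: int = 32,
                    kernels: tuple[int, ...] = (2, 4, 8),
                    blocks: int = 3, gru_layers: int = 4,
                    gru_units: int = 32) -> dict:
    """JSON-serializable architecture description of the ChronoNet.

    Each block concatenates ``len(kernels)`` stride-2 convolutions, so the
    temporal length is halved (ceil) per block; each GRU's input
    concatenates the outputs of all preceding GRU layers.
    """
    if n_timesteps < 2 ** blocks:
        raise ValueError(
            f"n_timesteps={n_timesteps} cannot support {blocks} stride-2 "
            f"reductions")
    lengths, width = [], n_channels
    length = n_timesteps
    block_descr = []
    for b in range(blocks):
        length = -(-length // 2)
        block_descr.append({
            "block": b,
            "convolutions": [{"kernel": k, "filters": filters, "stride": 2}
                             for k in kernels],
            "in_channels": width,
            "out_channels": filters * len(kernels),
            "out_length": length,
        })
        width = filters * len(kernels)
        lengths.append(length)
    gru_descr = []
    for g in range(gru_layers):
        d_in = width if g == 0 else min(g, gru_layers - 1) * gru_units
        gru_descr.append({"layer": g, "units": gru_units, "input_width": d_in})
    return {
        "inception_blocks": block_descr,
        "gru_layers": gru_descr,
        "dense": {"in": gru_units, "out": n_classes},
        "block_output_lengths": lengths,
    }


class ChronoNetModel(nn.layers.Module):
    """Inception-style conv blocks + densely connected GRUs + softmax head."""

    def __init__(self, n_channels: int, n_timesteps: int, n_classes: int,
                 seed: int, filters: int = 32, kernels: tuple[int, ...] = (2, 4, 8),
                 blocks: int = 3, gru_layers: int = 4, gru_units: int = 32,
                 dropout: float = 0.0):
        self.descr = build_chrononet(n_channels, n_timesteps, n_classes,
                                     filters, kernels, blocks, gru_layers,
                                     gru_units)
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = n_channels
        for _ in range(blocks):
            self.blocks.append([nn.Conv1d(rng, c_in, filters, k, stride=2)
                                for k in kernels])
            c_in = filters * len(kernels)
        self.grus = []
        for g in range(gru_layers):
            d_in = c_in if g == 0 else min(g, gru_layers - 1) * gru_units
            self.grus.append(nn.GRU(rng, d_in, gru_units))
        self.drop = nn.Dropout(dropout)
        self.head = nn.Dense(rng, gru_units, n_classes)

    def params(self):
        found = []
        for block in self.blocks:
            for conv in block:
                found.extend(conv.params())
        for gru in self.grus:
            found.extend(gru.params())
        found.extend(self.head.params())
        return found

    def forward(self, x, rng, training: bool):
        # x: (B, C, T)
        for block in self.blocks:
            x = ops.relu(ops.concat([conv(x) for conv in block], axis=1))
            x = self.drop(x, rng, training)
        x = ops.transpose(x, (0, 2, 1))  # (B, T', F)
        outputs = []
        for g, gru in enumerate(self.grus):
            inp = x if g == 0 else (
                outputs[0] if g == 1 else ops.concat(outputs[:g], axis=2))
            out = gru(inp)
            outputs.append(out)
        # temporal mean pooling of the last GRU sequence: a better-conditioned
        # readout than the final timestep for power-like discriminants
        pooled = ops.mean_time(outputs[-1])
        pooled = self.drop(pooled, rng, training)
        return self.head(pooled)


class StackedLSTMModel(nn.layers.Module):
    """Stacked LSTM layers with dropout, then a softmax head."""

    def __init__(self, n_features: int, n_classes: int, seed: int,
                 hidden: int = 64, layers: int = 2, dropout: float = 0.3):
        rng = np.random.default_rng(seed)
        self.lstms = []
        d_in = n_features
        for _ in range(layers):
            self.lstms.append(nn.LSTM(rng, d_in, hidden))
            d_in = hidden
        self.drop = nn.Dropout(dropout)
        self.head = nn.Dense(rng, hidden, n_classes)

    def params(self):
        found = []
        for lstm in self.lstms:
            found.extend(lstm.params())
        found.extend(self.head.params())
        return found

    def forward(self, x, rng, training: bool):
        # x: (B, T, D) — time steps carry per-channel samples
        for lstm in self.lstms:
            x = lstm(x)
            x = self.drop(x, rng, training)
        last = ops.select_time(x, x.shape[1] - 1)
        return self.head(last)


def _circular_shift(batch: np.ndarray, rng: np.random.Generator,
                    time_axis: int) -> np.ndarray:
    """Roll every sample by a random offset along its time axis."""
    out = np.empty_like(batch)
    n_t = batch.shape[time_axis]
    shifts = rng.integers(0, n_t, size=len(batch))
    for i, s in enumerate(shifts):
        out[i] = np.roll(batch[i], int(s), axis=time_axis - 1)
    return out


def _as_feature_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureTable):
        return X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(
            "feature-based models require 2-D inputs (samples x features); "
            f"got ndim={X.ndim}")
    return X


def _as_cycle_tensor(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(
            "sequence models require 3-D cycle tensors "
            f"(cycles x channels x time); got ndim={X.ndim}")
    return X


def _build_deep(spec: ModelSpec, n_ch: int, n_t: int, n_classes: int,
                hp: dict, seed: int):
    """Instantiate a sequence model with single-precision parameters."""
    if spec.kind == "chrononet":
        model = ChronoNetModel(
            n_ch, n_t, n_classes, seed,
            filters=hp["filters"], kernels=tuple(hp["kernels"]),
            blocks=hp["blocks"], gru_layers=hp["gru_layers"],
            gru_units=hp["gru_units"], dropout=hp["dropout"])
    else:
        model = StackedLSTMModel(
            n_ch, n_classes, seed, hidden=hp["hidden"],
            layers=hp["layers"], dropout=hp["dropout"])
    # single precision: halves training time, ample for classification
    for p in model.params():
        p.data = p.data.astype(np.float32)
    return model


def train(spec: ModelSpec, X, y) -> FittedModel:
    """Fit the classifier named by ``spec`` on features or cycle tensors."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    y_int = np.searchsorted(classes, y)
    hp = spec.hypers

    if spec.kind in DEEP_KINDS:
        Xt = _as_cycle_tensor(X)
        # per-channel standardization over cycles and time
        mean = Xt.mean(axis=(0, 2), keepdims=True)
        sd = Xt.std(axis=(0, 2), keepdims=True)
        sd[sd == 0] = 1.0
        Xs = (Xt - mean) / sd
        n_cycles, n_ch, n_t = Xs.shape
        if spec.kind == "chrononet":
            Xin = Xs.astype(np.float32)
        else:
            Xin = np.transpose(Xs, (0, 2, 1)).astype(np.float32)  # (B, T, C)
        # Random circular time shifts make the nets learn shift-invariant
        # (band-power-like) statistics instead of memorizing the phase-locked
        # waveforms of individual training cycles.
        time_axis = 2 if spec.kind == "chrononet" else 1
        augment = ((lambda b, rng: _circular_shift(b, rng, time_axis))
                   if hp.get("augment_shift") else None)
        # Non-convex training occasionally never escapes chance level from
        # an unlucky initialization; retry with a reseeded model (bounded,
        # judged on training accuracy only).
        chance = 1.0 / len(classes)
        for attempt in range(3):
            seed = spec.seed + 7919 * attempt
            model = _build_deep(spec, n_ch, n_t, len(classes), hp, seed)
            history = nn.fit_classifier(
                model, Xin, y_int, epochs=hp["epochs"],
                batch_size=hp["batch_size"], lr=hp["lr"],
                patience=hp["patience"], seed=seed, augment=augment)
            if history[-1]["train_accuracy"] >= chance + 0.08:
                break
        return FittedModel(spec, "cycle_tensor", classes, model,
                           scaler=(mean, sd), training_history=history)

    Xf = _as_feature_matrix(X)
    if spec.kind == "svm":
        mean, sd = Xf.mean(axis=0), Xf.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        impl = SVC(C=hp["C"], gamma=hp["gamma"], kernel="rbf",
                   probability=True, random_state=spec.seed)
        impl.fit((Xf - mean) / sd, y_int)
        return FittedModel(spec, "features", classes, impl, scaler=(mean, sd))
    if spec.kind == "random_forest":
        impl = RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_features=hp["max_features"],
            random_state=spec.seed, n_jobs=1)
        impl.fit(Xf, y_int)
        return FittedModel(spec, "features", classes, impl)
    impl = XGBClassifier(
        n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
        learning_rate=hp["learning_rate"], random_state=spec.seed,
        n_jobs=1, eval_metric="mlogloss", verbosity=0)
    impl.fit(Xf, y_int)
    return FittedModel(spec, "features", classes, impl)


def predict(model: FittedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class-score matrix (rows sum to 1).

    Ties in the score matrix break toward the lowest class index.
    """
    if model.input_contract == "cycle_tensor":
        Xt = _as_cycle_tensor(X)
        mean, sd = model.scaler
        Xs = ((Xt - mean) / sd).astype(np.float32)
        if model.spec.kind == "rnn_lstm":
            Xs = np.transpose(Xs, (0, 2, 1))
        scores = nn.predict_proba(model.impl, Xs).astype(np.float64)
    else:
        Xf = _as_feature_matrix(X)
        if model.spec.kind == "svm":
            mean, sd = model.scaler
            Xf = (Xf - mean) / sd
        scores = model.impl.predict_proba(Xf)
    scores = scores / scores.sum(axis=1, keepdims=True)
    labels = model.classes_[np.argmax(scores, axis=1)]
    return labels, scores
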