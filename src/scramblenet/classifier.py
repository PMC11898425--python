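"""Fully-connected classifier head on top of backbone features.

A multilayer perceptron with ReLU hidden layers and a softmax output over
the two classes, trained with mini-batch Adam on standardized features.
Training is an explicit epoch loop (so per-epoch loss/accuracy are logged
and NaN losses are caught with the offending epoch), fully reproducible
given the seed.  The optimization itself is delegated to scikit-learn's
MLP; prediction applies the documented tie-break (lowest class index on a
probability tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClassifierError",
    "DivergenceError",
    "DnnConfig",
    "TrainedModel",
    "train",
    "predict",
    "save_model",
    "load_model",
]


class ClassifierError(ValueError):
    """Invalid training inputs or configuration."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite; carries the offending epoch."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


@dataclass(frozen=True)
class DnnConfig:
    """Hyperparameters of the fully-connected head.

    hidden: sizes of the ReLU hidden layers (at least one required);
    epochs/batch_size/learning_rate/optimizer: Adam or SGD minibatch
    training; seed: controls init and shuffling, mandatory for
    reproducibility.
    """

    hidden: tuple = (256, 64)
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden) < 1 or any(h < 1 for h in self.hidden):
            raise ClassifierError("at least one positive hidden layer size required")
        if self.epochs < 1 or self.batch_size < 1:
            raise ClassifierError("epochs and batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ClassifierError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainedModel:
    """A fitted head: feature scaler + MLP + class order + training history.

    ``classes`` is sorted lexicographically and fixes both the probability
    column order and the argmax tie-break (ties go to the lowest index).
    """

    scaler: StandardScaler
    mlp: MLPClassifier
    classes: tuple
    config: DnnConfig
    history: list = field(default_factory=list)  # (epoch, loss, accuracy)

    @property
    def n_features(self) -> int:
        return int(self.scaler.mean_.shape[0])


def train(
    features: np.ndarray,
    labels: Sequence[str],
    config: DnnConfig | None = None,
) -> TrainedModel:
    """Fit the head on (features, labels).

    Requires at least two examples of each of the two classes.  Runs
    ``config.epochs`` passes over the shuffled training set, logging
    (epoch, training log-loss, training accuracy) into the returned model's
    history.  Identical inputs and seed give bit-identical fits.
    """
    if config is None:
        config = DnnConfig()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ClassifierError(
            f"features {x.shape} and labels {y.shape} are inconsistent"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassifierError(
            f"training set contains a single class {classes.tolist()}; "
            "need examples of both"
        )
    if len(classes) > 2:
        raise ClassifierError(f"expected binary labels, got {classes.tolist()}")
    if counts.min() < 2:
        raise ClassifierError("need at least 2 examples per class")

    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)

    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden),
        activation="relu",
        solver=config.optimizer,
        batch_size=min(config.batch_size, x.shape[0]),
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        max_iter=1,
        shuffle=True,
        warm_start=False,
    )
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(x.shape[0])
        mlp.partial_fit(xs[order], y[order], classes=classes)
        proba = mlp.predict_proba(xs)
        loss = float(log_loss(y, proba, labels=classes))
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        acc = float(np.mean(classes[np.argmax(proba, axis=1)] == y))
        history.append((epoch, loss, acc))
    return TrainedModel(
        scaler=scaler,
        mlp=mlp,
        classes=tuple(classes.tolist()),
        config=config,
        history=history,
    )


def predict(model: TrainedModel, features: np.ndarray):
    """Per-class probabilities and hard labels for a feature matrix.

    Probability rows are non-negative and sum to 1; hard labels are the
    argmax with ties broken toward the lowest class index.  Returns
    ``(proba, labels)`` where proba columns follow ``model.classes``.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.shape[1] != model.n_features:
        raise ClassifierError(
            f"feature length {x.shape[1]} does not match the "
            f"{model.n_features} the model was trained on"
        )
    proba = model.mlp.predict_proba(model.scaler.transform(x))
    # align probability columns with the stored class order
    col = [list(model.mlp.classes_).index(c) for c in model.classes]
    proba = proba[:, col]
    hard = np.array([model.classes[i] for i in np.argmax(proba, axis=1)])
    return proba, hard


# ---------------------------------------------------------------------------
# Model directory (runtime artifact: .npz parameters + JSON manifest)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {"scaler_mean": model.scaler.mean_, "scaler_scale": model.scaler.scale_}
    for i, (w, b) in enumerate(zip(model.mlp.coefs_, model.mlp.intercepts_)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(out / "parameters.npz", **arrays)
    manifest = {
        "classes": list(model.classes),
        "config": {
            "hidden": list(model.config.hidden),
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "learning_rate": model.config.learning_rate,
            "optimizer": model.config.optimizer,
            "seed": model.config.seed,
        },
        "n_layers": len(model.mlp.coefs_),
        "history": model.history,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def load_model(model_dir: str | Path) -> TrainedModel:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    data = np.load(model_dir / "parameters.npz")
    cfg = DnnConfig(
        hidden=tuple(manifest["config"]["hidden"]),
        epochs=manifest["config"]["epochs"],
        batch_size=manifest["config"]["batch_size"],
        learning_rate=manifest["config"]["learning_rate"],
        optimizer=manifest["config"]["optimizer"],
        seed=manifest["config"]["seed"],
    )
    scaler = StandardScaler()
    scaler.mean_ = data["scaler_mean"]
    scaler.scale_ = data["scaler_scale"]
    scaler.var_ = scaler.scale_ ** 2
    scaler.n_features_in_ = scaler.mean_.shape[0]

    classes = np.array(manifest["classes"])
    coefs = [data[f"w{i}"] for i in range(manifest["n_layers"])]
    intercepts = [data[f"b{i}"] for i in range(manifest["n_layers"])]
    mlp = MLPClassifier(hidden_layer_sizes=tuple(cfg.hidden), activation="relu")
    mlp.classes_ = classes
    mlp.coefs_ = coefs
    mlp.intercepts_ = intercepts
    mlp.n_layers_ = len(coefs) + 1
    mlp.n_outputs_ = 1 if len(classes) == 2 else len(classes)
    mlp.out_activation_ = "logistic" if len(classes) == 2 else "softmax"
    mlp._label_binarizer = _rebuild_binarizer(classes)
    return TrainedModel(
        scaler=scaler,
        mlp=mlp,
        classes=tuple(classes.tolist()),
        config=cfg,
        history=[tuple(h) for h in manifest["history"]],
    )


def _rebuild_binarizer(classes: np.ndarray):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(classes)
    return lb
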