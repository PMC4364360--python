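"""Backpropagation multilayer perceptron, written out explicitly.

The classifier is a fixed topology: one hidden layer of tanh-sigmoid units
(default 25) and a single linear output unit trained against 0/1 class
targets by full-batch gradient descent on the mean squared error.  Training
stops when the MSE reaches a goal or an epoch budget runs out.  The decision
rule thresholds the linear output at 0.5.

Inputs are min-max scaled to [0, 1] using bounds learned from the training
fold only (integer-coded categorical features at their raw scale would push
the tanh units into saturation); the bounds travel with the model so that
held-out data is scaled — and clipped — consistently.

All randomness (weight initialization) flows from a single integer seed, so a
given configuration, dataset and seed reproduce the trained weights bit for
bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and training hyperparameters of the MLP."""

    n_inputs: int
    n_hidden: int = 25
    learning_rate: float = 0.05
    max_epochs: int = 1000
    mse_goal: float = 1e-3
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("n_inputs and n_hidden must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if self.mse_goal <= 0:
            raise ValueError("mse_goal must be positive")


@dataclass
class NetworkModel:
    """Trained weights plus the input-normalization bounds they assume."""

    config: NetworkConfig
    w1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    feature_min: np.ndarray  # (n_inputs,)
    feature_max: np.ndarray  # (n_inputs,)

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            config=self.config,
            w1=self.w1.copy(),
            b1=self.b1.copy(),
            w2=self.w2.copy(),
            b2=float(self.b2),
            feature_min=self.feature_min.copy(),
            feature_max=self.feature_max.copy(),
        )


@dataclass(frozen=True)
class TrainRecord:
    """Per-epoch training MSE and why training stopped."""

    mse: tuple[float, ...]
    stop_reason: str  # "goal" | "max_epochs"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature min/max bounds from a training matrix."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    return X.min(axis=0), X.max(axis=0)


def normalize_apply(
    X: np.ndarray, feature_min: np.ndarray, feature_max: np.ndarray
) -> np.ndarray:
    """Min-max scale to [0, 1] with stored bounds; out-of-range values clip,
    constant features map to 0."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    span = feature_max - feature_min
    safe = np.where(span > 0, span, 1.0)
    Xn = (X - feature_min) / safe
    Xn = np.where(span > 0, Xn, 0.0)
    return np.clip(Xn, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Forward pass, loss and gradients
# ---------------------------------------------------------------------------


def init_network(config: NetworkConfig) -> NetworkModel:
    """Seeded uniform(−0.5, 0.5) weight initialization; bounds default to [0, 1]."""
    rng = np.random.default_rng(config.seed)
    return NetworkModel(
        config=config,
        w1=rng.uniform(-0.5, 0.5, size=(config.n_inputs, config.n_hidden)),
        b1=rng.uniform(-0.5, 0.5, size=config.n_hidden),
        w2=rng.uniform(-0.5, 0.5, size=config.n_hidden),
        b2=float(rng.uniform(-0.5, 0.5)),
        feature_min=np.zeros(config.n_inputs),
        feature_max=np.ones(config.n_inputs),
    )


def forward(model: NetworkModel, Xn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and linear output scores for normalized inputs."""
    hidden = np.tanh(Xn @ model.w1 + model.b1)
    scores = hidden @ model.w2 + model.b2
    return hidden, scores


def mse_loss(model: NetworkModel, Xn: np.ndarray, y: np.ndarray) -> float:
    _, scores = forward(model, Xn)
    return float(np.mean((scores - y) ** 2))


def gradients(
    model: NetworkModel, Xn: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic full-batch gradients of the MSE w.r.t. (w1, b1, w2, b2)."""
    n = Xn.shape[0]
    hidden, scores = forward(model, Xn)
    # dL/dscore for L = mean((score - y)^2)
    delta_out = 2.0 * (scores - y) / n  # (n,)
    gw2 = hidden.T @ delta_out  # (n_hidden,)
    gb2 = float(delta_out.sum())
    # backpropagate through the tanh layer
    delta_hidden = np.outer(delta_out, model.w2) * (1.0 - hidden**2)  # (n, n_hidden)
    gw1 = Xn.T @ delta_hidden  # (n_inputs, n_hidden)
    gb1 = delta_hidden.sum(axis=0)
    return gw1, gb1, gw2, gb2


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def train_bpnn(
    X: np.ndarray, y: Sequence[int], config: NetworkConfig
) -> tuple[NetworkModel, TrainRecord]:
    """Train by full-batch gradient descent on the MSE of the linear output.

    Targets must be 0/1.  Stops when the post-update training MSE reaches
    ``config.mse_goal`` or after ``config.max_epochs`` epochs.  Deterministic
    for a fixed (data, config) pair.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("feature matrix must be 2-D and nonempty")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have equal lengths")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if X.shape[1] != config.n_inputs:
        raise ValueError(f"expected {config.n_inputs} features, got {X.shape[1]}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")

    model = init_network(config)
    model.feature_min, model.feature_max = normalize_fit(X)
    Xn = normalize_apply(X, model.feature_min, model.feature_max)

    vel = [np.zeros_like(model.w1), np.zeros_like(model.b1), np.zeros_like(model.w2), 0.0]
    history: list[float] = []
    stop_reason = "max_epochs"
    for _ in range(config.max_epochs):
        gw1, gb1, gw2, gb2 = gradients(model, Xn, y)
        lr, mu = config.learning_rate, config.momentum
        vel[0] = mu * vel[0] - lr * gw1
        vel[1] = mu * vel[1] - lr * gb1
        vel[2] = mu * vel[2] - lr * gw2
        vel[3] = mu * vel[3] - lr * gb2
        model.w1 += vel[0]
        model.b1 += vel[1]
        model.w2 += vel[2]
        model.b2 += vel[3]
        mse = mse_loss(model, Xn, y)
        history.append(mse)
        if mse <= config.mse_goal:
            stop_reason = "goal"
            break
    return model, TrainRecord(mse=tuple(history), stop_reason=stop_reason)


def predict(model: NetworkModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores (linear output) and 0/1 labels (score >= 0.5) for raw features."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.config.n_inputs:
        raise ValueError(
            f"expected a 2-D matrix with {model.config.n_inputs} columns"
        )
    Xn = normalize_apply(X, model.feature_min, model.feature_max)
    _, scores = forward(model, Xn)
    labels = (scores >= 0.5).astype(int)
    return scores, labels


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_json(model: NetworkModel, path: str | Path | None = None) -> dict:
    payload = {
        "config": asdict(model.config),
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "feature_min": model.feature_min.tolist(),
        "feature_max": model.feature_max.tolist(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2))
    return payload


def model_from_json(source: str | Path | dict) -> NetworkModel:
    if isinstance(source, dict):
        payload = source
    else:
        payload = json.loads(Path(source).read_text())
    return NetworkModel(
        config=NetworkConfig(**payload["config"]),
        w1=np.asarray(payload["w1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        w2=np.asarray(payload["w2"], dtype=float),
        b2=float(payload["b2"]),
        feature_min=np.asarray(payload["feature_min"], dtype=float),
        feature_max=np.asarray(payload["feature_max"], dtype=float),
    )
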