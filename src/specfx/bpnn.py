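"""Backpropagation neural network for peak activity classification.

A deliberately minimal single-hidden-layer perceptron, written from scratch
on numpy: logistic-sigmoid hidden and output units, binary cross-entropy
loss, full-batch gradient descent, seeded uniform(-0.5, 0.5) weight
initialization.  The network classifies each common peak as class A (active)
or class B (inactive) from a 10-dimensional feature vector assembled from
the screening stages: 4 GRA grades, 4 VIP scores, the binding flag and the
relative content.  Features are min-max scaled to [0, 1] on the training
set.

The network is intentionally the textbook "BP" architecture - no momentum,
no regularization, no minibatching - so its behavior is exactly auditable
(gradients are verified against finite differences in the test suite).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingSet
from .errors import ConfigError, FitError, ValidationError
from .gra import GraResult
from .panel import INDICATORS
from .pls import VipResult

logger = logging.getLogger(__name__)

#: Fixed feature column order of the classifier input.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"gra_{m}" for m in INDICATORS] + [f"vip_{m}" for m in INDICATORS]
    + ["binding", "content"]
)

#: Class names: A = active, B = inactive.
CLASS_A, CLASS_B = "A", "B"


@dataclass
class FeatureTable:
    """Per-peak classifier features with their min-max scaling parameters."""

    peak_ids: list[int]
    raw: pd.DataFrame            # peaks x FEATURE_COLUMNS, unscaled
    scaled: np.ndarray           # same shape, mapped into [0, 1]
    f_min: np.ndarray
    f_max: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)


def assemble_features(
    gra: GraResult,
    vips: Mapping[str, VipResult],
    binding: BindingSet,
    content: np.ndarray,
    peak_ids: Sequence[int] | None = None,
) -> FeatureTable:
    """Build the classification dataset: one row per peak, 10 features.

    All sources must cover the same peak ids; a missing peak raises an error
    naming it.  A constant feature column is scaled to 0 with a warning
    (degenerate min-max).
    """
    if peak_ids is None:
        peak_ids = [int(j) for j in gra.grades.columns]
    peak_ids = [int(j) for j in peak_ids]
    content = np.asarray(content, dtype=float)
    if content.size != len(peak_ids):
        raise ValidationError(
            f"content has {content.size} entries for {len(peak_ids)} peaks"
        )
    cols: dict[str, np.ndarray] = {}
    for ind in INDICATORS:
        missing = [j for j in peak_ids if j not in gra.grades.columns]
        if missing:
            raise ValidationError(f"GRA grades missing peaks {missing}")
        cols[f"gra_{ind}"] = gra.grades.loc[ind, peak_ids].to_numpy(dtype=float)
    for ind in INDICATORS:
        if ind not in vips:
            raise ValidationError(f"VIP results missing indicator {ind!r}")
        res = vips[ind]
        ids = res.peak_ids or list(range(1, res.vip.size + 1))
        lookup = {int(j): float(v) for j, v in zip(ids, res.vip)}
        missing = [j for j in peak_ids if j not in lookup]
        if missing:
            raise ValidationError(f"VIP scores for {ind!r} missing peaks {missing}")
        cols[f"vip_{ind}"] = np.array([lookup[j] for j in peak_ids])
    cols["binding"] = np.array([1.0 if j in binding else 0.0 for j in peak_ids])
    cols["content"] = content
    raw = pd.DataFrame(cols, index=pd.Index(peak_ids, name="peak_id"))[list(FEATURE_COLUMNS)]
    arr = raw.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite feature values")
    f_min = arr.min(axis=0)
    f_max = arr.max(axis=0)
    span = f_max - f_min
    const = np.flatnonzero(span == 0)
    if const.size:
        warnings.warn(
            f"constant feature column(s) {[FEATURE_COLUMNS[i] for i in const]}; scaled to 0",
            stacklevel=2,
        )
    safe = np.where(span == 0, 1.0, span)
    scaled = (arr - f_min) / safe
    scaled[:, const] = 0.0
    return FeatureTable(peak_ids=peak_ids, raw=raw, scaled=scaled, f_min=f_min, f_max=f_max)


@dataclass(frozen=True)
class BpnnConfig:
    """Training hyperparameters (single hidden layer, sigmoid/sigmoid)."""

    hidden_units: int = 8
    learning_rate: float = 1.0
    epochs: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


@dataclass
class BpnnModel:
    """Trained network parameters plus the scaling of its inputs."""

    w1: np.ndarray  # d x h
    b1: np.ndarray  # h
    w2: np.ndarray  # h
    b2: float
    loss_history: np.ndarray
    f_min: np.ndarray | None = None
    f_max: np.ndarray | None = None
    config: BpnnConfig = field(default_factory=BpnnConfig)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def loss_and_grads(
    params: Mapping[str, np.ndarray], X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean binary cross-entropy and its analytic gradients.

    Exposed as a pure function of the parameter dict so the backprop
    derivation can be checked against finite differences.
    """
    w1, b1, w2, b2 = params["w1"], params["b1"], params["w2"], params["b2"]
    n = X.shape[0]
    z1 = X @ w1 + b1
    h = _sigmoid(z1)
    z2 = h @ w2 + float(b2)
    # stable BCE with logits: mean(softplus(z2) - y*z2)
    loss = float(np.mean(np.logaddexp(0.0, z2) - y * z2))
    d2 = (_sigmoid(z2) - y) / n            # dL/dz2
    gw2 = h.T @ d2
    gb2 = float(d2.sum())
    dh = np.outer(d2, w2)
    d1 = dh * h * (1.0 - h)                # dL/dz1
    gw1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return loss, {"w1": gw1, "b1": gb1, "w2": gw2, "b2": np.asarray(gb2)}


def _coerce_labels(labels: Iterable) -> np.ndarray:
    out = []
    for v in labels:
        if isinstance(v, str):
            if v.upper() == CLASS_A:
                out.append(1)
            elif v.upper() == CLASS_B:
                out.append(0)
            else:
                raise ValidationError(f"unknown class label {v!r} (expected A or B)")
        else:
            out.append(int(v))
    arr = np.asarray(out, dtype=float)
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValidationError("labels must be binary (A/1 = active, B/0 = inactive)")
    return arr


def train(
    features: FeatureTable | np.ndarray,
    labels: Iterable,
    config: BpnnConfig = BpnnConfig(),
) -> BpnnModel:
    """Train by full-batch gradient descent with backpropagation.

    Deterministic under a fixed seed (weights and biases initialized from
    seeded uniform(-0.5, 0.5)).  Raises on single-class labels and on
    divergence (non-finite loss).
    """
    if isinstance(features, FeatureTable):
        X = features.scaled
        f_min, f_max = features.f_min, features.f_max
    else:
        X = np.asarray(features, dtype=float)
        f_min = f_max = None
    y = _coerce_labels(labels)
    if y.size != X.shape[0]:
        raise ValidationError(f"{X.shape[0]} feature rows but {y.size} labels")
    n_a, n_b = int(y.sum()), int((1 - y).sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"need at least 2 peaks per class (got A={n_a}, B={n_b})"
        )
    rng = np.random.default_rng(config.seed)
    d, h = X.shape[1], config.hidden_units
    params = {
        "w1": rng.uniform(-0.5, 0.5, size=(d, h)),
        "b1": rng.uniform(-0.5, 0.5, size=h),
        "w2": rng.uniform(-0.5, 0.5, size=h),
        "b2": np.asarray(rng.uniform(-0.5, 0.5)),
    }
    history = np.empty(config.epochs)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        loss, grads = loss_and_grads(params, X, y)
        if not np.isfinite(loss):
            raise FitError(
                f"training diverged (non-finite loss at epoch {epoch}); "
                "try a smaller learning_rate"
            )
        history[epoch] = loss
        for k in params:
            params[k] = params[k] - lr * grads[k]
    return BpnnModel(
        w1=params["w1"], b1=params["b1"], w2=params["w2"], b2=float(params["b2"]),
        loss_history=history, f_min=f_min, f_max=f_max, config=config,
    )


def predict_proba(model: BpnnModel, features: FeatureTable | np.ndarray) -> np.ndarray:
    """P(class A) per peak; FeatureTable inputs are used as already scaled."""
    X = features.scaled if isinstance(features, FeatureTable) else np.asarray(features, dtype=float)
    h = _sigmoid(X @ model.w1 + model.b1)
    return _sigmoid(h @ model.w2 + model.b2)


def predict_class(model: BpnnModel, features: FeatureTable | np.ndarray) -> np.ndarray:
    """"A"/"B" per peak; a tie at exactly 0.5 goes to B (conservative)."""
    p = predict_proba(model, features)
    return np.where(p > 0.5, CLASS_A, CLASS_B)


@dataclass
class Evaluation:
    """2x2 confusion matrix (rows = true, columns = predicted) + summaries."""

    matrix: pd.DataFrame
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]


def evaluate(
    model: BpnnModel, features: FeatureTable | np.ndarray, labels: Iterable
) -> Evaluation:
    """Confusion matrix of the model on labelled peaks.

    Rows are the true classes (A then B), columns the predicted classes;
    precision/recall reported per class (0 when undefined).
    """
    y = _coerce_labels(labels)
    pred = predict_class(model, features)
    true = np.where(y == 1.0, CLASS_A, CLASS_B)
    classes = (CLASS_A, CLASS_B)
    mat = pd.DataFrame(
        [[int(np.sum((true == t) & (pred == p))) for p in classes] for t in classes],
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    total = int(mat.to_numpy().sum())
    accuracy = float(np.trace(mat.to_numpy())) / total if total else 0.0
    precision = {}
    recall = {}
    for c in classes:
        col = int(mat[c].sum())
        row = int(mat.loc[c].sum())
        precision[c] = float(mat.loc[c, c]) / col if col else 0.0
        recall[c] = float(mat.loc[c, c]) / row if row else 0.0
    return Evaluation(matrix=mat, accuracy=accuracy, precision=precision, recall=recall)
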