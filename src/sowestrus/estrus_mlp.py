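"""Lightweight MLP estrus classifier with L1-magnitude pruning.

The classifier maps the two vulvar features (aspect ratio, red
saturation), min-max normalised on the training split, to an estrus
probability through a small fully connected network (2 -> 16 -> 8 -> 1,
ReLU hidden activations, sigmoid output).  A sow is called in estrus when
the probability reaches 0.5.

Pruning zeroes every weight whose magnitude is at or below a threshold
lambda; lambda may be given directly or derived as a quantile of |W| over
all layers jointly (L1-norm ranking).  A short fine-tune with the zero
pattern frozen recovers most of the lost accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "MLPModel",
    "Normalizer",
    "PruneSpec",
    "TrainConfig",
    "forward",
    "predict_proba",
    "train",
    "l1_prune",
    "fine_tune",
]


@dataclass
class Normalizer:
    """Per-feature min-max scaling fitted on the training split."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Normalizer":
        mins = x.min(axis=0)
        maxs = x.max(axis=0)
        if np.any(maxs <= mins):
            raise ValueError("degenerate feature range (max <= min)")
        return cls(mins, maxs)

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mins) / (self.maxs - self.mins)
        if np.any(z < 0) or np.any(z > 1):
            warnings.warn("features outside the training range; clipping", stacklevel=2)
            z = np.clip(z, 0.0, 1.0)
        return z


@dataclass
class PruneSpec:
    """Either an absolute magnitude threshold or a target sparsity."""

    threshold: float | None = None
    sparsity: float | None = None

    def __post_init__(self):
        if (self.threshold is None) == (self.sparsity is None):
            raise ValueError("give exactly one of threshold or sparsity")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.sparsity is not None and not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must be in [0, 1)")


@dataclass
class TrainConfig:
    hidden: tuple = (16, 8)
    epochs: int = 300
    batch_size: int = 32
    lr: float = 1e-2


class MLPModel(nn.Module):
    def __init__(self, layer_sizes: tuple, rng: np.random.Generator):
        self.layers = [
            nn.Linear(a, b, rng) for a, b in zip(layer_sizes[:-1], layer_sizes[1:])
        ]
        self.layer_sizes = tuple(layer_sizes)
        # pruning masks (1 = keep); populated by l1_prune
        self.masks = [np.ones_like(l.weight.data) for l in self.layers]

    def logits(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers[:-1]:
            h = layer(h).relu()
        return self.layers[-1](h)

    def apply_masks(self):
        for layer, mask in zip(self.layers, self.masks):
            layer.weight.data *= mask

    def weight_arrays(self) -> list:
        return [l.weight.data for l in self.layers]

    def save(self, path, norm: "Normalizer | None" = None):
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "weights": [l.weight.data.tolist() for l in self.layers],
            "biases": [l.bias.data.tolist() for l in self.layers],
            "masks": [m.tolist() for m in self.masks],
        }
        if norm is not None:
            payload["normalizer"] = {
                "mins": norm.mins.tolist(),
                "maxs": norm.maxs.tolist(),
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> tuple:
        payload = json.loads(Path(path).read_text())
        model = cls(tuple(payload["layer_sizes"]), np.random.default_rng(0))
        for layer, w, b, m in zip(
            model.layers, payload["weights"], payload["biases"], payload["masks"]
        ):
            layer.weight.data[...] = np.asarray(w)
            layer.bias.data[...] = np.asarray(b)
        model.masks = [np.asarray(m) for m in payload["masks"]]
        norm = None
        if "normalizer" in payload:
            norm = Normalizer(
                np.asarray(payload["normalizer"]["mins"]),
                np.asarray(payload["normalizer"]["maxs"]),
            )
        return model, norm


def forward(model: MLPModel, x, norm: Normalizer | None = None) -> np.ndarray:
    """Estrus probabilities for feature rows x (shape (n, 2) or (2,))."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"expected {model.layer_sizes[0]} features, got {x.shape[1]}"
        )
    if norm is not None:
        x = norm.transform(x)
    z = model.logits(Tensor(x)).sigmoid()
    return z.data.reshape(-1)


predict_proba = forward


def train(
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple:
    """Train on (n, 2) features and binary labels; returns (model, normalizer).

    Binary cross-entropy, Adam, fixed-seed shuffling; deterministic for a
    given seed.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float).reshape(-1)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    norm = Normalizer.fit(features)
    x_all = norm.transform(features)
    sizes = (features.shape[1], *config.hidden, 1)
    model = MLPModel(sizes, rng)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    n = len(labels)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.logits(Tensor(x_all[idx]))
            loss = nn.logistic_bce(logits, labels[idx].reshape(-1, 1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.apply_masks()  # no-op unless pruned
    return model, norm


def l1_prune(model: MLPModel, spec: PruneSpec) -> tuple:
    """Zero weights with |w| <= lambda; returns (model, report).

    lambda is the given threshold, or the `sparsity` quantile of |W| over
    all layers jointly.  Rejects thresholds that would remove every
    weight.  The report maps layer index -> zero fraction and includes the
    effective threshold.
    """
    all_w = np.concatenate([np.abs(w).ravel() for w in model.weight_arrays()])
    lam = (
        spec.threshold
        if spec.threshold is not None
        else float(np.quantile(all_w, spec.sparsity))
    )
    if lam >= all_w.max():
        raise ValueError(
            f"threshold {lam:.4g} >= max|W| {all_w.max():.4g}: all weights would vanish"
        )
    report = {"threshold": lam, "per_layer_zero_fraction": {}}
    for i, (layer, _) in enumerate(zip(model.layers, model.masks)):
        mask = (np.abs(layer.weight.data) > lam).astype(float)
        model.masks[i] = mask
        layer.weight.data *= mask
        report["per_layer_zero_fraction"][i] = float(1.0 - mask.mean())
    report["overall_zero_fraction"] = float(
        1.0
        - np.concatenate([m.ravel() for m in model.masks]).mean()
    )
    return model, report


def fine_tune(
    model: MLPModel,
    norm: Normalizer,
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = 30,
    batch_size: int = 32,
    lr: float = 3e-3,
    seed: int = 0,
) -> MLPModel:
    """Continue training with the pruned zero pattern frozen."""
    rng = np.random.default_rng(seed)
    x_all = norm.transform(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=float).reshape(-1)
    opt = nn.Adam(model.parameters(), lr=lr)
    n = len(labels)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.logits(Tensor(x_all[idx]))
            loss = nn.logistic_bce(logits, labels[idx].reshape(-1, 1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.apply_masks()
    return model
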