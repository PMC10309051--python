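"""Compact CNN patch classifier: three 64-filter convolutional layers and
two dense layers (128, 96) feeding a 2-way softmax head.

The network is deliberately small — it trains on a few thousand crops on an
ordinary CPU and is less prone to overfitting than deeper architectures.
Each convolution is 3x3 with same padding, followed by ReLU and 2x2
max-pooling; training uses Adam on class-weighted cross-entropy, so an
unbalanced dataset (more background than animal crops, as is typical for
cluttered habitats) does not bias the head.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import LABELS, LabelledCrop
from .nn import Adam, Conv2D, Dense, Flatten, MaxPool2, Network, ReLU
from .nn import load_network, save_network

__all__ = [
    "ModelSpec", "TrainingReport", "ClassifierModel", "build_model",
    "split_dataset", "augment", "augment_dataset", "train", "predict",
    "predict_batch", "save_model", "load_model",
]

#: class indices: 0 = background ("no"), 1 = animal ("yes")
CLASS_OF_LABEL = {"no": 0, "yes": 1}

AUGMENT_OPS = ("flip-h", "flip-v", "rot90", "rot180", "rot270")


@dataclass
class ModelSpec:
    """Architecture constants of the compact network.

    The three convolutional layers all carry 64 filters; the two hidden
    dense layers funnel 128 -> 96 toward the 2-class softmax head.
    """

    input_side: int = 21
    channels: int = 1
    conv_filters: tuple[int, int, int] = (64, 64, 64)
    dense_units: tuple[int, int] = (128, 96)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("exactly three convolutional layers are required")
        if len(self.dense_units) != 2:
            raise ValueError("exactly two dense layers are required")
        if any(not 96 <= u <= 128 for u in self.dense_units):
            raise ValueError("dense layer widths must lie in [96, 128]")
        if self.n_classes != 2:
            raise ValueError("the classifier is strictly two-category")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 (grayscale) or 3 (colour)")


@dataclass
class TrainingReport:
    epochs: int
    train_accuracy: float
    validation_accuracy: float
    n_train: int
    n_val: int
    seed: int
    wall_seconds: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class ClassifierModel:
    """A trained (or freshly initialized) network plus its input contract."""

    net: Network
    input_side: int
    channels: int = 1


def build_model(spec: ModelSpec, seed: int = 0) -> ClassifierModel:
    """Assemble the network with seeded He-normal initialization.

    The input side must be at least 8 so three rounds of 2x2 pooling leave
    a non-empty feature map.
    """
    if spec.input_side < 8:
        raise ValueError(
            f"input_side must be >= 8 to survive three 2x2 poolings, "
            f"got {spec.input_side}"
        )
    rng = np.random.default_rng(seed)
    layers = []
    cin = spec.channels
    side = spec.input_side
    for cout in spec.conv_filters:
        layers += [Conv2D(cin, cout, 3, rng=rng), ReLU(), MaxPool2()]
        cin = cout
        side //= 2
    flat = side * side * cin
    layers.append(Flatten())
    d_in = flat
    for units in spec.dense_units:
        layers += [Dense(d_in, units, rng=rng), ReLU()]
        d_in = units
    layers.append(Dense(d_in, spec.n_classes, rng=rng))
    return ClassifierModel(Network(layers), spec.input_side, spec.channels)


def split_dataset(crops: Sequence[LabelledCrop], val_fraction: float,
                  seed: int = 0) -> tuple[list[LabelledCrop], list[LabelledCrop]]:
    """Stratified train/validation split (class ratio preserved within 1)."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    rng = np.random.default_rng(seed)
    train: list[LabelledCrop] = []
    val: list[LabelledCrop] = []
    for label in LABELS:
        members = [c for c in crops if c.label == label]
        if len(members) < 2:
            raise ValueError(f"class {label!r} has {len(members)} samples; need >= 2")
        order = rng.permutation(len(members))
        n_val = max(1, int(round(val_fraction * len(members))))
        val += [members[i] for i in order[:n_val]]
        train += [members[i] for i in order[n_val:]]
    return train, val


def _brightness(pixels: np.ndarray, delta: float) -> np.ndarray:
    shifted = pixels.astype(np.float64) + delta
    if np.issubdtype(pixels.dtype, np.integer):
        return np.clip(np.round(shifted), 0, 255).astype(pixels.dtype)
    return np.clip(shifted, 0.0, 255.0).astype(pixels.dtype)


def augment(crop: LabelledCrop, ops: Sequence[str],
            seed: int | None = None) -> list[LabelledCrop]:
    """One label-preserving variant per requested op.

    Ops: ``flip-h``, ``flip-v``, ``rot90``, ``rot180``, ``rot270`` and
    ``brightness±δ`` (e.g. ``brightness+10``). All are deterministic;
    ``seed`` is accepted for interface symmetry with the other generators.
    """
    out = []
    for op in ops:
        p = crop.pixels
        if op == "flip-h":
            q = p[:, ::-1].copy()
        elif op == "flip-v":
            q = p[::-1, :].copy()
        elif op in ("rot90", "rot180", "rot270"):
            q = np.rot90(p, k=int(op[3:]) // 90).copy()
        elif op.startswith("brightness"):
            try:
                delta = float(op[len("brightness"):])
            except ValueError:
                raise ValueError(f"bad brightness op {op!r}") from None
            q = _brightness(p, delta)
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
        out.append(LabelledCrop(q, crop.label, crop.frame_index, crop.center))
    return out


def augment_dataset(crops: Sequence[LabelledCrop],
                    ops: Sequence[str]) -> list[LabelledCrop]:
    """Originals plus every augmented variant (per-class counts only grow)."""
    out = list(crops)
    for crop in crops:
        out += augment(crop, ops)
    return out


def _as_arrays(crops: Sequence[LabelledCrop], input_side: int,
               channels: int) -> tuple[np.ndarray, np.ndarray]:
    xs = np.empty((len(crops), input_side, input_side, channels), dtype=np.float32)
    ys = np.empty(len(crops), dtype=np.int64)
    for i, crop in enumerate(crops):
        p = crop.pixels
        if p.ndim == 2:
            p = p[..., None]
        if p.shape != (input_side, input_side, channels):
            raise ValueError(
                f"crop {i} has shape {crop.pixels.shape}, model expects "
                f"{input_side}x{input_side}x{channels}"
            )
        xs[i] = p.astype(np.float32) / 255.0
        ys[i] = CLASS_OF_LABEL[crop.label]
    return xs, ys


def _accuracy(model: ClassifierModel, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> float:
    hits = 0
    for i in range(0, len(x), batch):
        probs = model.net.predict_proba(x[i:i + batch])
        hits += int((probs.argmax(axis=1) == y[i:i + batch]).sum())
    return hits / len(x) if len(x) else float("nan")


def train(
    model: ClassifierModel,
    train_set: Sequence[LabelledCrop],
    val_set: Sequence[LabelledCrop],
    epochs: int = 10,
    seed: int = 0,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    class_weighting: bool = True,
    verbose: bool = False,
) -> tuple[ClassifierModel, TrainingReport]:
    """Train in place with Adam on class-weighted cross-entropy.

    Per-class weights are inversely proportional to class frequency, so a
    background-heavy dataset (recommended for cluttered habitats) does not
    drown out the animal class. ``epochs=0`` evaluates without updating.
    """
    t0 = time.time()
    x_tr, y_tr = _as_arrays(train_set, model.input_side, model.channels)
    x_va, y_va = _as_arrays(val_set, model.input_side, model.channels)
    counts = np.bincount(y_tr, minlength=2)
    if epochs > 0 and counts.min() == 0:
        raise ValueError("training set must contain both classes")
    weights = None
    if class_weighting and counts.min() > 0:
        weights = counts.sum() / (2.0 * counts)
    rng = np.random.default_rng(seed)
    opt = Adam(model.net.params, lr=learning_rate)
    for epoch in range(epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), batch_size):
            sel = order[i:i + batch_size]
            loss = model.net.loss_and_grad(x_tr[sel], y_tr[sel], weights)
            opt.step(model.net.grads)
            losses.append(loss)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  loss {np.mean(losses):.4f}")
    report = TrainingReport(
        epochs=epochs,
        train_accuracy=_accuracy(model, x_tr, y_tr),
        validation_accuracy=_accuracy(model, x_va, y_va),
        n_train=len(train_set),
        n_val=len(val_set),
        seed=seed,
        wall_seconds=time.time() - t0,
    )
    return model, report


def predict_batch(model: ClassifierModel, crops: np.ndarray) -> np.ndarray:
    """Probabilities for a batch of raw crops (N, side, side[, channels]).

    Returns an (N, 2) array of (p_background, p_animal) rows summing to 1.
    """
    x = np.asarray(crops)
    if x.ndim == 3:
        x = x[..., None]
    expected = (model.input_side, model.input_side, model.channels)
    if x.shape[1:] != expected:
        raise ValueError(f"crops have shape {x.shape[1:]}, model expects {expected}")
    return model.net.predict_proba(x.astype(np.float32) / 255.0)


def predict(model: ClassifierModel,
            crop: np.ndarray) -> tuple[float, float]:
    """(p_animal, p_background) for one crop; the pair sums to 1."""
    probs = predict_batch(model, np.asarray(crop)[None])[0]
    return float(probs[1]), float(probs[0])


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    return save_network(model.net, path,
                        meta={"input_side": model.input_side,
                              "channels": model.channels})


def load_model(path: str | Path) -> ClassifierModel:
    net, meta = load_network(path)
    return ClassifierModel(net, int(meta["input_side"]), int(meta["channels"]))


def append_report(report: TrainingReport, path: str | Path) -> None:
    """Append the report as one JSON-lines record."""
    with open(path, "a") as fh:
        fh.write(report.to_json() + "\n")
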