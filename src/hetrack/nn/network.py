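"""Sequential network container, weighted softmax loss, Adam, (de)serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Conv2D, Dense, Flatten, Layer, MaxPool2, ReLU

__all__ = ["Network", "Adam", "softmax", "save_network", "load_network"]

_LAYER_TAGS = {Conv2D: "conv", ReLU: "relu", MaxPool2: "maxpool2",
               Flatten: "flatten", Dense: "dense"}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """A plain sequential stack of layers with a softmax head."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(np.asarray(x, dtype=np.float32)))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return dlogits

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray,
                      class_weights: np.ndarray | None = None) -> float:
        """Weighted mean cross-entropy; leaves gradients in each layer.

        ``class_weights[c]`` rescales the loss of class-``c`` samples;
        the mean is taken over total sample weight so the gradient scale
        is independent of the batch composition.
        """
        logits = self.forward(x)
        probs = softmax(logits)
        n = x.shape[0]
        w = np.ones(n, dtype=np.float64) if class_weights is None else class_weights[y]
        wsum = w.sum()
        eps = 1e-12
        loss = float(-(w * np.log(probs[np.arange(n), y] + eps)).sum() / wsum)
        dlogits = probs.astype(np.float64)
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (w / wsum)[:, None]
        self.backward(dlogits.astype(logits.dtype))
        return loss

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    """Adam with the standard bias correction (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _describe(net: Network) -> list[dict]:
    arch = []
    for layer in net.layers:
        tag = _LAYER_TAGS[type(layer)]
        entry: dict = {"type": tag}
        if isinstance(layer, Conv2D):
            entry.update(in_channels=layer.w.shape[2], out_channels=layer.w.shape[3],
                         kernel=layer.kernel)
        elif isinstance(layer, Dense):
            entry.update(in_features=layer.w.shape[0], out_features=layer.w.shape[1])
        arch.append(entry)
    return arch


def _rebuild(arch: list[dict]) -> Network:
    rng = np.random.default_rng(0)  # weights overwritten right after
    layers: list[Layer] = []
    for entry in arch:
        tag = entry["type"]
        if tag == "conv":
            layers.append(Conv2D(entry["in_channels"], entry["out_channels"],
                                 entry["kernel"], rng=rng))
        elif tag == "dense":
            layers.append(Dense(entry["in_features"], entry["out_features"], rng=rng))
        elif tag == "relu":
            layers.append(ReLU())
        elif tag == "maxpool2":
            layers.append(MaxPool2())
        elif tag == "flatten":
            layers.append(Flatten())
        else:
            raise ValueError(f"unknown layer tag {tag!r}")
    return Network(layers)


def save_network(net: Network, path: str | Path,
                 meta: dict | None = None) -> Path:
    """Persist architecture + weights (+ JSON metadata) to one ``.npz`` file."""
    path = Path(path)
    arrays = {f"param_{i}": p for i, p in enumerate(net.params)}
    arrays["arch"] = np.frombuffer(
        json.dumps({"layers": _describe(net), "meta": meta or {}}).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    return path


def load_network(path: str | Path) -> tuple[Network, dict]:
    """Inverse of :func:`save_network`; predictions are bit-identical."""
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["arch"]).decode())
        net = _rebuild(header["layers"])
        for i, p in enumerate(net.params):
            p[...] = data[f"param_{i}"]
    return net, header["meta"]
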