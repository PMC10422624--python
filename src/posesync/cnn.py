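"""1-D convolutional classifier mapping 17 synchrony scores to an emotion.

Architecture: three 1-D convolution layers (kernel 3, filters 32, 64,
64, ReLU) with max-pooling (size 2) after the first two, a flatten, and
dense layers of 64, 32 and n_classes units with a softmax head.  With
same-padding the length trace for 17 input features is
17 -> 17 -> 8 -> 8 -> 4 -> 4 -> flatten 256.  Training uses categorical
cross-entropy, the Adam optimizer at learning rate 1e-4, batch size 100
and 20 epochs.

The network, its backward pass and Adam are implemented directly in
numpy; the 17 features are treated as a length-17 single-channel
sequence in canonical body-part order (convolution is order-sensitive,
so the order is fixed and documented in the skeleton module).  Runs are
deterministic for a fixed seed on single-threaded BLAS; multi-threaded
reductions may differ in the last few ulps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelSpec",
    "CNN1D",
    "build_model",
    "TrainingHistory",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed hyperparameters of the classifier."""

    n_features: int = 17
    n_classes: int = 3
    conv_filters: tuple[int, int, int] = (32, 64, 64)
    kernel: int = 3
    pool: int = 2
    dense_units: tuple[int, int] = (64, 32)
    learning_rate: float = 1e-4
    batch_size: int = 100
    epochs: int = 20


def _length_trace(spec: ModelSpec) -> list[int]:
    """Sequence lengths after each conv/pool stage (same-padding convs)."""
    L = spec.n_features
    trace = [L]
    trace.append(L)            # conv1 (same)
    L = L // spec.pool
    trace.append(L)            # pool1
    trace.append(L)            # conv2
    L = L // spec.pool
    trace.append(L)            # pool2
    trace.append(L)            # conv3
    return trace


def _conv_same(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (B, C_in, L); W: (C_out, C_in, k); same (zero) padding
    pad = W.shape[2] // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, W.shape[2], axis=2)  # (B, C_in, L, k)
    return np.einsum("bclk,ock->bol", win, W, optimize=True) + b[None, :, None]


def _conv_same_backward(x, W, dz):
    pad = W.shape[2] // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, W.shape[2], axis=2)
    dW = np.einsum("bclk,bol->ock", win, dz, optimize=True)
    db = dz.sum(axis=(0, 2))
    dzp = np.pad(dz, ((0, 0), (0, 0), (pad, pad)))
    dwin = sliding_window_view(dzp, W.shape[2], axis=2)  # (B, C_out, L, k)
    dx = np.einsum("bolk,ock->bcl", dwin, W[:, :, ::-1], optimize=True)
    return dx, dW, db


def _maxpool(x: np.ndarray, size: int):
    B, C, L = x.shape
    L2 = L // size
    xr = x[:, :, : L2 * size].reshape(B, C, L2, size)
    arg = xr.argmax(axis=3)
    return xr.max(axis=3), (arg, L)


def _maxpool_backward(dz: np.ndarray, cache, size: int):
    arg, L = cache
    B, C, L2 = dz.shape
    dxr = np.zeros((B, C, L2, size), dtype=dz.dtype)
    np.put_along_axis(dxr, arg[..., None], dz[..., None], axis=3)
    dx = np.zeros((B, C, L), dtype=dz.dtype)
    dx[:, :, : L2 * size] = dxr.reshape(B, C, L2 * size)
    return dx


class CNN1D:
    """The classifier: parameters, forward pass, backward pass, Adam."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.n_features < 8:
            trace = _length_trace(spec)
            raise ValueError(
                "input too short for the conv/pool stack: need n_features >= 8, "
                f"got {spec.n_features} (length trace {trace})"
            )
        if spec.n_classes < 2:
            raise ValueError("need at least two classes")
        self.spec = spec
        self.length_trace = _length_trace(spec)
        self.classes_: list | None = None
        rng = np.random.default_rng(seed)
        f1, f2, f3 = spec.conv_filters
        k = spec.kernel
        flat = self.length_trace[-1] * f3
        d1, d2 = spec.dense_units

        def uniform(shape, fan_in):
            lim = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-lim, lim, size=shape)

        self.params: dict[str, np.ndarray] = {
            "W1": uniform((f1, 1, k), 1 * k), "b1": np.zeros(f1),
            "W2": uniform((f2, f1, k), f1 * k), "b2": np.zeros(f2),
            "W3": uniform((f3, f2, k), f2 * k), "b3": np.zeros(f3),
            "Wd1": uniform((flat, d1), flat), "bd1": np.zeros(d1),
            "Wd2": uniform((d1, d2), d1), "bd2": np.zeros(d2),
            "Wd3": uniform((d2, spec.n_classes), d2),
            "bd3": np.zeros(spec.n_classes),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Class probabilities for a (B, n_features) batch."""
        p = self.params
        x = X[:, None, :]                                   # (B, 1, L)
        z1 = _conv_same(x, p["W1"], p["b1"]); a1 = np.maximum(z1, 0)
        p1, c1 = _maxpool(a1, self.spec.pool)
        z2 = _conv_same(p1, p["W2"], p["b2"]); a2 = np.maximum(z2, 0)
        p2, c2 = _maxpool(a2, self.spec.pool)
        z3 = _conv_same(p2, p["W3"], p["b3"]); a3 = np.maximum(z3, 0)
        flat = a3.reshape(len(X), -1)
        h1 = flat @ p["Wd1"] + p["bd1"]; r1 = np.maximum(h1, 0)
        h2 = r1 @ p["Wd2"] + p["bd2"]; r2 = np.maximum(h2, 0)
        logits = r2 @ p["Wd3"] + p["bd3"]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        if cache is not None:
            cache.update(x=x, z1=z1, c1=c1, p1=p1, z2=z2, c2=c2, p2=p2,
                         z3=z3, a3=a3, flat=flat, h1=h1, r1=r1, h2=h2,
                         r2=r2, probs=probs)
        return probs

    def _backward(self, cache: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        B = len(y_onehot)
        g: dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot) / B
        g["Wd3"] = cache["r2"].T @ dlogits; g["bd3"] = dlogits.sum(0)
        dr2 = dlogits @ p["Wd3"].T
        dh2 = dr2 * (cache["h2"] > 0)
        g["Wd2"] = cache["r1"].T @ dh2; g["bd2"] = dh2.sum(0)
        dr1 = dh2 @ p["Wd2"].T
        dh1 = dr1 * (cache["h1"] > 0)
        g["Wd1"] = cache["flat"].T @ dh1; g["bd1"] = dh1.sum(0)
        dflat = dh1 @ p["Wd1"].T
        da3 = dflat.reshape(cache["a3"].shape)
        dz3 = da3 * (cache["z3"] > 0)
        dp2, g["W3"], g["b3"] = _conv_same_backward(cache["p2"], p["W3"], dz3)
        da2 = _maxpool_backward(dp2, cache["c2"], self.spec.pool)
        dz2 = da2 * (cache["z2"] > 0)
        dp1, g["W2"], g["b2"] = _conv_same_backward(cache["p1"], p["W2"], dz2)
        da1 = _maxpool_backward(dp1, cache["c1"], self.spec.pool)
        dz1 = da1 * (cache["z1"] > 0)
        _, g["W1"], g["b1"] = _conv_same_backward(cache["x"], p["W1"], dz1)
        return g

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        lr = self.spec.learning_rate
        for k_, gval in grads.items():
            m = self._adam_m[k_] = b1 * self._adam_m[k_] + (1 - b1) * gval
            v = self._adam_v[k_] = b2 * self._adam_v[k_] + (1 - b2) * gval ** 2
            mhat = m / (1 - b1 ** self._adam_t)
            vhat = v / (1 - b2 ** self._adam_t)
            self.params[k_] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        return self.forward(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        if self.classes_ is not None:
            return np.asarray(self.classes_)[idx]
        return idx


def build_model(n_features: int = 17, n_classes: int = 3, seed: int = 0) -> CNN1D:
    """Build the classifier with the fixed architecture."""
    return CNN1D(ModelSpec(n_features=n_features, n_classes=n_classes), seed=seed)


@dataclass
class TrainingHistory:
    """Per-epoch metrics plus the final test confusion matrix."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    seed: int = 0
    confusion: np.ndarray | None = None  # rows true, columns predicted

    def __len__(self) -> int:
        return len(self.train_loss)


def _encode_labels(y, classes: list) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[v] for v in y])
    except KeyError as exc:
        raise ValueError(f"label {exc} outside the class set {classes}") from None


def _metrics(model: CNN1D, X: np.ndarray, y_idx: np.ndarray) -> tuple[float, float]:
    probs = model.forward(X)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y_idx))
    return loss, acc


def train(
    model: CNN1D,
    X_train, y_train,
    X_test, y_test,
    seed: int = 0,
) -> TrainingHistory:
    """Train for the spec's fixed number of epochs; record metrics.

    Features are expected min-max scaled to [0, 1].  Labels may be
    strings or integers; the class order is the sorted unique training
    labels.  A test label outside the training class set raises.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    classes = sorted(set(y_train))
    if len(classes) > model.spec.n_classes:
        raise ValueError(
            f"{len(classes)} observed classes exceed the model's "
            f"{model.spec.n_classes} outputs"
        )
    # pad the class list so indexing matches the softmax width
    while len(classes) < model.spec.n_classes:
        classes.append(f"_unused_{len(classes)}")
    model.classes_ = classes
    yi_train = _encode_labels(y_train, classes)
    yi_test = _encode_labels(y_test, classes)
    onehot = np.eye(model.spec.n_classes)

    rng = np.random.default_rng(seed)
    hist = TrainingHistory(seed=seed)
    n = len(X_train)
    bs = model.spec.batch_size
    for _ in range(model.spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            rows = order[start : start + bs]
            cache: dict = {}
            self_probs = model.forward(X_train[rows], cache)
            grads = model._backward(cache, onehot[yi_train[rows]])
            model._adam_step(grads)
        tl, ta = _metrics(model, X_train, yi_train)
        vl, va = _metrics(model, X_test, yi_test)
        hist.train_loss.append(tl); hist.train_acc.append(ta)
        hist.test_loss.append(vl); hist.test_acc.append(va)
    _, hist.confusion = evaluate(model, X_test, y_test)
    return hist


def evaluate(model: CNN1D, X, y) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows = true, columns = predicted)."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if model.classes_ is None:
        raise ValueError("model has not been trained")
    yi = _encode_labels(y, model.classes_)
    pred = model.forward(X).argmax(axis=1)
    k = model.spec.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (yi, pred), 1)
    accuracy = float(np.trace(confusion) / confusion.sum())
    return accuracy, confusion
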