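"""CNN filter for clustered intra-alignment signatures, in pure numpy.

The network consumes the (100, 25) cluster feature matrix and outputs one of
{DEL, INS, false}. Backbone: three convolutional layers with kernels 3x25,
3x8 and 3x1, each followed by max-pooling, then three fully connected layers
(256 -> 64 -> 3) with batch normalization and dropout. The first convolution
collapses the 25-feature axis into 8 channels; those channels are treated as
the width of the second convolution's input, so the 3x8 kernel mixes them
while sliding along the signature axis. Training uses cross-entropy, Adam,
batch size 256, 15 epochs, and a fixed-step learning-rate decay (x0.1 every
5 epochs). Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..clustering import SignatureCluster
from .matrix import CLUSTER_MATRIX_ROWS, ClusterFeatureMatrix, N_INTRA, \
    build_cluster_matrix

CNN_CLASSES = ("DEL", "INS", "false")

BATCH_SIZE = 256
EPOCHS = 15
LEARNING_RATE = 1e-3
LR_DECAY_STEP = 5
LR_DECAY_FACTOR = 0.1
DROPOUT_P = 0.5


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, c_in, c_out, kh, kw, rng):
        super().__init__()
        fan_in = c_in * kh * kw
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(c_out, c_in, kh, kw)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.kh, self.kw = kh, kw

    def forward(self, x, train):
        self._x = x
        sw = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        self._sw = sw
        out = np.einsum("nchwij,ocij->nohw", sw, self.params["W"],
                        optimize=True)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        w = self.params["W"]
        self.grads["W"] = np.einsum("nohw,nchwij->ocij", dout, self._sw,
                                    optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.zeros_like(self._x)
        _, _, ho, wo = dout.shape
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i:i + ho, j:j + wo] += np.einsum(
                    "nohw,oc->nchw", dout, w[:, :, i, j], optimize=True)
        return dx


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPoolRows(_Layer):
    """Max-pool with kernel (2, 1), stride (2, 1); odd trailing rows dropped."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        h2 = h // 2
        self._in_shape = x.shape
        xr = x[:, :, : h2 * 2].reshape(n, c, h2, 2, w)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        h2 = h // 2
        dxr = np.zeros((n, c, h2, 2, w), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :], dout[:, :, :, None, :],
                          axis=3)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : h2 * 2] = dxr.reshape(n, c, h2 * 2, w)
        return dx


class ChannelsToWidth(_Layer):
    """(N, C, H, 1) -> (N, 1, H, C): conv channels become spatial width."""

    def forward(self, x, train):
        self._shape = x.shape
        n, c, h, _ = x.shape
        return x[:, :, :, 0].transpose(0, 2, 1)[:, None, :, :]

    def backward(self, dout):
        return dout[:, 0].transpose(0, 2, 1)[:, :, :, None]


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in),
                                      size=(n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class BatchNorm1D(_Layer):
    def __init__(self, n, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n, dtype=np.float32)
        self.params["beta"] = np.zeros(n, dtype=np.float32)
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        n = dout.shape[0]
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        dxhat = dout * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=0)
                - xhat * (dxhat * xhat).mean(axis=0)) / self._std


class Dropout(_Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class CNNModel:
    layers: list = field(default_factory=list)
    heldout_accuracy: float = 0.0
    final_loss: float = 0.0

    @classmethod
    def build(cls, rng) -> "CNNModel":
        layers = [
            Conv2D(1, 8, 3, N_INTRA, rng), ReLU(), MaxPoolRows(),
            ChannelsToWidth(),
            Conv2D(1, 16, 3, 8, rng), ReLU(), MaxPoolRows(),
            Conv2D(16, 32, 3, 1, rng), ReLU(), MaxPoolRows(),
            Flatten(),
            Dense(320, 256, rng), BatchNorm1D(256), ReLU(), Dropout(DROPOUT_P, rng),
            Dense(256, 64, rng), BatchNorm1D(64), ReLU(), Dropout(DROPOUT_P, rng),
            Dense(64, len(CNN_CLASSES), rng),
        ]
        return cls(layers=layers)

    def forward(self, x, train=False):
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, matrices: np.ndarray, batch: int = 512) -> np.ndarray:
        x = matrices.reshape(-1, 1, CLUSTER_MATRIX_ROWS, N_INTRA).astype(np.float32)
        out = []
        for i in range(0, len(x), batch):
            out.append(_softmax(self.forward(x[i:i + batch], train=False)))
        return np.vstack(out) if out else np.empty((0, len(CNN_CLASSES)))

    def predict(self, matrices: np.ndarray) -> list[str]:
        proba = self.predict_proba(matrices)
        return [CNN_CLASSES[i] for i in proba.argmax(axis=1)]

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, val in layer.params.items():
                state[f"{i}.{name}"] = val
            if isinstance(layer, BatchNorm1D):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        state["heldout_accuracy"] = np.array(self.heldout_accuracy)
        state["final_loss"] = np.array(self.final_loss)
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"])
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = np.asarray(state[f"{i}.running_mean"])
                layer.running_var = np.asarray(state[f"{i}.running_var"])
        self.heldout_accuracy = float(state.get("heldout_accuracy", 0.0))
        self.final_loss = float(state.get("final_loss", 0.0))


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


def train_cnn(matrices: Sequence[ClusterFeatureMatrix], seed: int = 0,
              epochs: int = EPOCHS, batch_size: int = BATCH_SIZE,
              heldout_fraction: float = 0.2) -> CNNModel:
    """Train the filter CNN on labeled cluster matrices.

    Deterministic under ``seed`` (weight init, shuffling, dropout, the
    held-out split). Raises on single-class input.
    """
    labels = [m.label for m in matrices]
    if any(l not in CNN_CLASSES for l in labels):
        raise ValueError("labels must be in {DEL, INS, false}")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    rng = np.random.default_rng(seed)
    x = np.stack([m.values for m in matrices]).astype(np.float32)
    x = x[:, None, :, :]
    y = np.array([CNN_CLASSES.index(l) for l in labels])

    idx = rng.permutation(len(x))
    n_val = max(1, int(round(heldout_fraction * len(x))))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    x_tr, y_tr = x[tr_idx], y[tr_idx]

    model = CNNModel.build(rng)
    opt = _Adam(model.layers, LEARNING_RATE)
    last_loss = 0.0
    for epoch in range(epochs):
        opt.lr = LEARNING_RATE * (LR_DECAY_FACTOR ** (epoch // LR_DECAY_STEP))
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), batch_size):
            sel = order[i:i + batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits = model.forward(xb, train=True)
            proba = _softmax(logits)
            loss = -np.mean(np.log(proba[np.arange(len(yb)), yb] + 1e-12))
            losses.append(loss)
            dlogits = proba.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.backward((dlogits / len(yb)).astype(np.float32))
            opt.step()
        last_loss = float(np.mean(losses))
    model.final_loss = last_loss
    preds = np.argmax(model.predict_proba(x[val_idx, 0]), axis=1)
    model.heldout_accuracy = float(np.mean(preds == y[val_idx]))
    return model


def cnn_filter(clusters: Sequence[SignatureCluster], model: CNNModel,
               bounds: np.ndarray) -> list[SignatureCluster]:
    """Apply the CNN to intra-sourced DEL/INS clusters.

    "false" predictions drop the cluster, a type prediction conflicting with
    the cluster's nominal type relabels it; DUP/INV/TRA clusters and clusters
    without intra evidence pass through untouched.
    """
    kept = []
    scorable = []
    for cl in clusters:
        intra = [m for m in cl.members
                 if m.source == "intra" and m.features is not None]
        if cl.t in ("DEL", "INS") and intra:
            scorable.append((cl, intra))
        else:
            kept.append(cl)
    if not scorable:
        return kept
    mats = []
    for cl, intra in scorable:
        sub = SignatureCluster(t=cl.t, c=cl.c, members=intra,
                               consensus_s=cl.consensus_s,
                               consensus_e=cl.consensus_e)
        mats.append(build_cluster_matrix(sub, bounds).values)
    preds = model.predict(np.stack(mats))
    for (cl, _), pred in zip(scorable, preds):
        if pred == "false":
            continue
        if pred != cl.t:
            cl.t = pred
        kept.append(cl)
    return kept
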