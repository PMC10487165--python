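"""Compact convolutional neural network for food-type classification and
caloric regression, implemented in NumPy.

Architecture (64x64 inputs, C channels):

    conv 11x11 -> ReLU -> maxpool 4x4 -> conv 7x7 -> ReLU -> maxpool 4x4
    -> flatten -> FC(112) -> ReLU -> FC(128) -> ReLU -> output(Nt)

The output layer is a soft-max over Nt food classes (cross-entropy loss) or
a single linear unit predicting kcal (mean-absolute-percentage-error loss).
Training uses mini-batch Adam with seeded He initialisation; given the same
seed and data the loss trace is bit-reproducible on one machine.

Convolutions are valid (stride 1, no padding), evaluated in the Fourier
domain; pooling uses stride = window with floor truncation, so the spatial
path is 64 -> 54 -> 13 -> 7 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from sklearn.metrics import confusion_matrix as _confusion_matrix


@dataclass
class CnnConfig:
    task: str  # "classification" or "regression"
    n_targets: int
    input_channels: int
    input_size: int = 64
    conv1_kernel: int = 11
    conv2_kernel: int = 7
    pool: int = 4
    conv1_filters: int = 16
    conv2_filters: int = 32
    fc_sizes: tuple[int, int] = (112, 128)
    epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "regression" and self.n_targets != 1:
            raise ValueError("regression uses a single output")
        size = self.input_size
        for k in (self.conv1_kernel, self.conv2_kernel):
            size = size - k + 1
            if size <= 0:
                raise ValueError("kernel larger than remaining spatial size")
            size //= self.pool
            if size <= 0:
                raise ValueError("pooling collapses the spatial size to zero")
        self.final_spatial = size


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv:
    """Valid cross-correlation (stride 1, no padding).

    Both passes run in the Fourier domain: with the inputs zero-padded to
    the frame size there is no circular wrap-around inside the valid region,
    so the FFT route is numerically the plain spatial convolution, just far
    cheaper than an im2col matmul at these kernel sizes (11x11, 7x7).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_in, c_out, k, k))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2:]
        self._hw = (h, w)
        self._xh = sp_fft.rfft2(x, s=(h, w))            # (N, C, h, wf)
        self._kh = sp_fft.rfft2(self.w, s=(h, w))       # (C, F, h, wf)
        out = sp_fft.irfft2(
            np.einsum("ncxy,cfxy->nfxy", self._xh, np.conj(self._kh)),
            s=(h, w))
        hp, wp = h - self.k + 1, w - self.k + 1
        return out[:, :, :hp, :wp] + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        dh = sp_fft.rfft2(dout, s=(h, w))               # zero-pads to frame size
        self.db = dout.sum(axis=(0, 2, 3))
        dk_full = sp_fft.irfft2(
            np.einsum("ncxy,nfxy->cfxy", self._xh, np.conj(dh)), s=(h, w))
        self.dw = np.ascontiguousarray(dk_full[:, :, :self.k, :self.k])
        dx = sp_fft.irfft2(np.einsum("nfxy,cfxy->ncxy", dh, self._kh), s=(h, w))
        return dx.astype(np.float32)

    def params(self):
        return [("w", self), ("b", self)]


class _MaxPool:
    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.p
        n, c, h, w = x.shape
        hp, wp = h // p, w // p
        self._x_shape = x.shape
        xr = x[:, :, :hp * p, :wp * p].reshape(n, c, hp, p, wp, p)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hp, wp, p * p)
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.p
        n, c, hp, wp = dout.shape
        dxr = np.zeros((n, c, hp, wp, p * p), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, hp, wp, p, p).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        dx[:, :, :hp * p, :wp * p] = dxr.reshape(n, c, hp * p, wp * p)
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class FoodCnn:
    """The two-conv CNN; ``forward`` returns class probabilities
    (classification) or kcal predictions (regression)."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        c = config
        s1 = c.input_size - c.conv1_kernel + 1
        p1 = s1 // c.pool
        s2 = p1 - c.conv2_kernel + 1
        p2 = s2 // c.pool
        flat = c.conv2_filters * p2 * p2
        self.layers = [
            _Conv(c.input_channels, c.conv1_filters, c.conv1_kernel, rng),
            _ReLU(), _MaxPool(c.pool),
            _Conv(c.conv1_filters, c.conv2_filters, c.conv2_kernel, rng),
            _ReLU(), _MaxPool(c.pool),
            _Flatten(),
            _Dense(flat, c.fc_sizes[0], rng), _ReLU(),
            _Dense(c.fc_sizes[0], c.fc_sizes[1], rng), _ReLU(),
            _Dense(c.fc_sizes[1], c.n_targets, rng),
        ]
        self._adam_state: dict | None = None

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        if out.ndim != 4 or out.shape[1] != self.config.input_channels \
                or out.shape[2:] != (self.config.input_size,) * 2:
            raise ValueError(
                f"expected (N, {self.config.input_channels}, "
                f"{self.config.input_size}, {self.config.input_size}) input, "
                f"got {out.shape}")
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x)
        if self.config.task == "classification":
            return _softmax(z)
        return z[:, 0]

    predict = forward

    def n_parameters(self) -> int:
        return sum(getattr(obj, name).size
                   for layer in self.layers for name, obj in layer.params())

    # -- training internals -------------------------------------------------
    def _backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def _adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        if self._adam_state is None:
            self._adam_state = {}
        for li, layer in enumerate(self.layers):
            for name, obj in layer.params():
                g = getattr(obj, "d" + name)
                key = (li, name)
                m, v = self._adam_state.get(key, (np.zeros_like(g), np.zeros_like(g)))
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                self._adam_state[key] = (m, v)
                mh = m / (1 - beta1 ** t)
                vh = v / (1 - beta2 ** t)
                p = getattr(obj, name)
                setattr(obj, name, p - lr * mh / (np.sqrt(vh) + eps))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(config: CnnConfig) -> FoodCnn:
    return FoodCnn(config)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mape(truth: Sequence[float], pred: Sequence[float]) -> float:
    """Mean absolute percentage error, 100 * mean(|truth - pred| / truth).

    Zero (or negative) ground truth is rejected: zeros must have been
    replaced by the nutrition-table minimum upstream.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have the same length")
    if (truth <= 0).any():
        raise ValueError("MAPE undefined for zero ground truth; "
                         "replace zero calories first")
    return float(100.0 * np.mean(np.abs(truth - pred) / truth))


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p, 1e-12, None))))


def _loss_and_grad(model: FoodCnn, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = model.logits(x)
    n = len(y)
    if model.config.task == "classification":
        p = _softmax(z)
        loss = cross_entropy(p, y)
        grad = p.copy()
        grad[np.arange(n), y] -= 1.0
        return loss, (grad / n).astype(np.float32)
    pred = z[:, 0].astype(float)
    loss = mape(y, pred)
    grad = (100.0 * np.sign(pred - y) / y / n)[:, None]
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: FoodCnn
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss

    @property
    def final_val_loss(self) -> float:
        return float(self.history.val_loss.iloc[-1])


def train(model: FoodCnn, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray,
          config: CnnConfig | None = None) -> TrainResult:
    """Mini-batch Adam training; returns the model plus per-epoch train and
    validation loss.  Reproducible given ``config.seed``."""
    config = config or model.config
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation splits must be non-empty")
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    if config.task == "classification":
        y_train = np.asarray(y_train, dtype=int)
        y_val = np.asarray(y_val, dtype=int)
    else:
        y_train = np.asarray(y_train, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if (y_train <= 0).any() or (y_val <= 0).any():
            raise ValueError("zero/negative caloric labels: run "
                             "replace_zero_calories before training")
        # start the output unit at the mean target so relative errors begin O(1)
        model.layers[-1].b[:] = np.float32(y_train.mean())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n = len(x_train)
    t = 0
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grad = _loss_and_grad(model, x_train[idx], y_train[idx])
            model._backward(grad)
            t += 1
            model._adam_step(config.learning_rate, t)
            epoch_loss += loss * len(idx)
        val_loss, _ = _loss_and_grad(model, x_val, y_val)
        rows.append((epoch, epoch_loss / n, val_loss))
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    return TrainResult(model=model, history=history)


@dataclass
class EvalReport:
    task: str
    overall: float            # accuracy (%) or MAPE (%)
    per_item: pd.Series       # per-item accuracy (%) or per-item MAPE (%)
    pearson_r: float | None = None
    confusion: np.ndarray | None = None
    cumulative_mape: pd.DataFrame | None = None  # columns: mape, fraction


def evaluate(model: FoodCnn, x: np.ndarray, y: np.ndarray,
             item_ids: np.ndarray | None = None) -> EvalReport:
    """Evaluate a trained model on one split.

    Classification: overall/per-item accuracy (%) and a confusion matrix.
    Regression: overall/per-item MAPE (%), Pearson r between truth and
    prediction, and the cumulative MAPE distribution.
    """
    if len(x) == 0:
        raise ValueError("empty evaluation split")
    task = model.config.task
    item_ids = np.asarray(item_ids if item_ids is not None else
                          (y if task == "classification" else np.zeros(len(x), int)))
    out = model.forward(np.asarray(x, dtype=np.float32))
    if task == "classification":
        y = np.asarray(y, dtype=int)
        pred = out.argmax(axis=1)
        correct = (pred == y).astype(float)
        per_item = pd.Series(correct, index=item_ids).groupby(level=0).mean() * 100
        return EvalReport(task=task, overall=float(correct.mean() * 100),
                          per_item=per_item,
                          confusion=_confusion_matrix(y, pred,
                                                      labels=np.arange(model.config.n_targets)))
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("zero caloric ground truth: replace zeros first")
    ape = 100.0 * np.abs(y - out) / y
    per_item = pd.Series(ape, index=item_ids).groupby(level=0).mean()
    if y.std() > 0 and out.std() > 0:
        r = float(np.corrcoef(y, out)[0, 1])
    else:
        r = None
    order = np.sort(ape)
    cum = pd.DataFrame({"mape": order,
                        "fraction": np.arange(1, len(order) + 1) / len(order)})
    return EvalReport(task=task, overall=float(ape.mean()), per_item=per_item,
                      pearson_r=r, cumulative_mape=cum)
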