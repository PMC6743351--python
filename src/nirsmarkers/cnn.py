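"""A small convolutional network for 48x48 image biomarkers, in numpy.

Architecture: two convolutional layers and two fully connected layers, with
ReLU activations, max-pooling, dropout and a softmax cross-entropy loss,
trained with Adam at batch size 4.  The default convolution is the
text-CNN-style row filter -- kernel width equal to the input width and
height ``h`` (so ``output_i = w . x[i:i+h-1]``, a 1-D slide over rows); a
conventional 3x3 2-D mode is available via ``mode="2d"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CnnConfig:
    mode: str = "row"                     # "row" (width = input width) | "2d"
    n_filters: tuple[int, int] = (8, 16)
    kernel_h: int = 3
    pool: int = 2
    dropout: float = 0.25
    hidden: int = 32
    batch_size: int = 4
    learning_rates: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    epochs: int = 50
    patience: int = 10
    beta1: float = 0.9
    beta2: float = 0.999                  # see docs/methods.md on this default
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.mode not in ("row", "2d"):
            raise ValueError("mode must be 'row' or '2d'")


class _Conv:
    """Valid convolution via precomputed gather indices (im2col)."""

    def __init__(self, in_shape, kh, kw, n_filters, rng):
        H, W, C = in_shape
        self.out_h, self.out_w = H - kh + 1, W - kw + 1
        if self.out_h < 1 or self.out_w < 1:
            raise ValueError("kernel larger than input")
        fan_in = kh * kw * C
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, n_filters))
        self.b = np.zeros(n_filters)
        self.out_shape = (self.out_h, self.out_w, n_filters)
        idx = np.empty((self.out_h * self.out_w, fan_in), dtype=np.int64)
        p = 0
        for i in range(self.out_h):
            for j in range(self.out_w):
                q = 0
                for a in range(kh):
                    for b_ in range(kw):
                        base = ((i + a) * W + (j + b_)) * C
                        idx[p, q:q + C] = base + np.arange(C)
                        q += C
                p += 1
        self.idx = idx
        self.in_size = H * W * C

    def forward(self, x):           # x: (N, H, W, C)
        N = x.shape[0]
        flat = x.reshape(N, -1)
        self.cols = flat[:, self.idx]                   # (N, P, Q)
        out = self.cols @ self.W + self.b               # (N, P, F)
        self.mask = out > 0
        return (out * self.mask).reshape(N, *self.out_shape)

    def backward(self, dout):
        N = dout.shape[0]
        d = dout.reshape(N, -1, self.W.shape[1]) * self.mask
        self.dW = np.einsum("npq,npf->qf", self.cols, d) / N
        self.db = d.sum(axis=(0, 1)) / N
        dcols = d @ self.W.T                            # (N, P, Q)
        dx = np.zeros((N, self.in_size))
        np.add.at(dx, (np.arange(N)[:, None, None], self.idx[None]), dcols)
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _MaxPool:
    def __init__(self, in_shape, ph, pw):
        H, W, C = in_shape
        self.ph, self.pw = ph, pw
        self.h2, self.w2 = H // ph, W // pw
        self.crop = (self.h2 * ph, self.w2 * pw)
        self.out_shape = (self.h2, self.w2, C)

    def forward(self, x):
        N, _, _, C = x.shape
        xc = x[:, :self.crop[0], :self.crop[1], :]
        r = xc.reshape(N, self.h2, self.ph, self.w2, self.pw, C)
        out = r.max(axis=(2, 4))
        self.mask = (r == out[:, :, None, :, None, :])
        self.mask = self.mask / np.maximum(self.mask.sum(axis=(2, 4),
                                                         keepdims=True), 1)
        self.in_shape = x.shape[1:]
        return out

    def backward(self, dout):
        N = dout.shape[0]
        dr = self.mask * dout[:, :, None, :, None, :]
        dx = np.zeros((N, *self.in_shape))
        dx[:, :self.crop[0], :self.crop[1], :] = dr.reshape(
            N, self.crop[0], self.crop[1], -1)
        return dx.reshape(N, -1)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng, relu=True):
        self.W = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu

    def forward(self, x):
        self.x = x
        out = x @ self.W + self.b
        if self.relu:
            self.mask = out > 0
            out = out * self.mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self.mask
        self.dW = self.x.T @ dout / dout.shape[0]
        self.db = dout.mean(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class SmallCnn:
    """Two-conv / two-FC binary classifier on (N, 48, 48) images."""

    def __init__(self, config: CnnConfig = CnnConfig(), *,
                 input_shape: tuple[int, int] = (48, 48),
                 rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        self.rng = rng
        H, W = input_shape
        kh = config.kernel_h
        f1, f2 = config.n_filters
        shape = (H, W, 1)
        if config.mode == "row":
            # filter width equals the (current) input width in both layers
            self.conv1 = _Conv(shape, kh, W, f1, rng)
            pool1 = _MaxPool(self.conv1.out_shape, config.pool, 1)
            self.conv2 = _Conv(pool1.out_shape, kh, pool1.out_shape[1], f2, rng)
            pool2 = _MaxPool(self.conv2.out_shape, config.pool, 1)
        else:
            self.conv1 = _Conv(shape, kh, kh, f1, rng)
            pool1 = _MaxPool(self.conv1.out_shape, config.pool, config.pool)
            self.conv2 = _Conv(pool1.out_shape, kh, kh, f2, rng)
            pool2 = _MaxPool(self.conv2.out_shape, config.pool, config.pool)
        self.pool1, self.pool2 = pool1, pool2
        n_flat = int(np.prod(pool2.out_shape))
        self.fc1 = _Dense(n_flat, config.hidden, rng, relu=True)
        self.fc2 = _Dense(config.hidden, 2, rng, relu=False)
        self.layers = [self.conv1, self.pool1, self.conv2, self.pool2,
                       self.fc1, self.fc2]
        self._adam: dict[int, tuple] = {}
        self._step = 0

    # -- forward / backward -------------------------------------------------
    def _forward(self, x, train):
        cfg = self.config
        a = self.conv1.forward(x[..., None])
        a = self.pool1.forward(a)
        a = self._dropout(a, train, 0)
        a = self.conv2.forward(a)
        a = self.pool2.forward(a)
        a = self._dropout(a, train, 1)
        a = a.reshape(a.shape[0], -1)
        a = self.fc1.forward(a)
        return self.fc2.forward(a)

    def _dropout(self, a, train, slot):
        p = self.config.dropout
        if not train or p == 0:
            return a
        mask = (self.rng.random(a.shape) >= p) / (1 - p)
        setattr(self, f"_dmask{slot}", mask)
        return a * mask

    def _backward(self, dlogits):
        d = self.fc2.backward(dlogits)
        d = self.fc1.backward(d)
        d = d.reshape(-1, *self.pool2.out_shape)
        if self.config.dropout:
            d = d * self._dmask1
        d = self.pool2.backward(d)
        d = self.conv2.backward(d).reshape(-1, *self.pool1.out_shape)
        if self.config.dropout:
            d = d * self._dmask0
        d = self.pool1.backward(d)
        self.conv1.backward(d)

    def _adam_update(self, lr):
        cfg = self.config
        self._step += 1
        t = self._step
        for li, layer in enumerate(self.layers):
            for name, w, gname in layer.params():
                g = getattr(layer, gname)
                key = (li, name)
                m, v = self._adam.get(key, (np.zeros_like(w), np.zeros_like(w)))
                m = cfg.beta1 * m + (1 - cfg.beta1) * g
                v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
                self._adam[key] = (m, v)
                mhat = m / (1 - cfg.beta1 ** t)
                vhat = v / (1 - cfg.beta2 ** t)
                w -= lr * mhat / (np.sqrt(vhat) + cfg.eps)

    # -- public API ---------------------------------------------------------
    def fit(self, X, y, *, lr, X_val=None, y_val=None,
            epochs: int | None = None) -> float:
        """Train with Adam; early-stops on validation accuracy when given.

        Returns the best validation accuracy (or final training accuracy when
        no validation set is supplied).
        """
        cfg = self.config
        epochs = epochs or cfg.epochs
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        best_val, best_state, stale = -np.inf, None, 0
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for i in range(0, n, cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                logits = self._forward(X[idx], train=True)
                z = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(axis=1, keepdims=True)
                d = p.copy()
                d[np.arange(len(idx)), y[idx]] -= 1.0
                self._backward(d)
                self._adam_update(lr)
            if X_val is not None:
                acc = float((self.predict(X_val) == y_val).mean())
                if acc > best_val:
                    best_val, stale = acc, 0
                    best_state = self._snapshot()
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
        if best_state is not None:
            self._restore(best_state)
            return best_val
        return float((self.predict(X) == y).mean())

    def predict(self, X) -> np.ndarray:
        logits = self._forward(np.asarray(X, dtype=float), train=False)
        return logits.argmax(axis=1)

    def _snapshot(self):
        return [(li, name, w.copy()) for li, layer in enumerate(self.layers)
                for name, w, _ in layer.params()]

    def _restore(self, state):
        for li, name, w in state:
            for pname, param, _ in self.layers[li].params():
                if pname == name:
                    param[...] = w
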