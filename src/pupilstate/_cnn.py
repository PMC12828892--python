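"""Minimal 1-D convolutional network for band-power trial classification.

A small stack of conv(kernel 7) + ReLU + max-pool(3) blocks, global average
pooling, one dense ReLU layer and a single sigmoid output, trained with
binary cross-entropy and Adam (minibatch 32, at most 100 epochs, early
stopping on validation accuracy with the best weights retained).  Written
directly on NumPy; all randomness flows from one generator so training is
bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _sliding(x, k, axis):
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=axis)


class _Conv1D:
    def __init__(self, c_in, c_out, k, rng):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_out, c_in, k)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)

    def forward(self, x):                      # x: (B, C, L)
        self._cols = _sliding(x, self.W.shape[2], axis=2)  # (B,C,L',k)
        out = np.einsum("bcit,oct->boi", self._cols, self.W,
                        optimize=True) + self.b[None, :, None]
        return out

    def backward(self, dout):                  # dout: (B, O, L')
        k = self.W.shape[2]
        self.dW = np.einsum("boi,bcit->oct", dout, self._cols, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        dpad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        cols2 = _sliding(dpad, k, axis=2)      # (B,O,L,k)
        Wf = self.W[:, :, ::-1]
        return np.einsum("boju,ocu->bcj", cols2, Wf, optimize=True)

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m

    def params(self):
        return []


class _MaxPool:
    def __init__(self, size=3):
        self.size = size

    def forward(self, x):                      # (B, C, L)
        s = self.size
        B, C, L = x.shape
        Lp = L // s
        self._shape = x.shape
        xr = x[:, :, :Lp * s].reshape(B, C, Lp, s)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dout):                  # (B, C, Lp)
        s = self.size
        B, C, L = self._shape
        Lp = dout.shape[2]
        dx = np.zeros((B, C, Lp, s), dtype=dout.dtype)
        bi, ci, li = np.ogrid[:B, :C, :Lp]
        dx[bi, ci, li, self._arg] = dout
        dx = dx.reshape(B, C, Lp * s)
        if Lp * s < L:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, L - Lp * s)))
        return dx

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x):                      # (B, C, L) -> (B, C)
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / F32(self._L)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)

    def forward(self, x):                      # (B, n_in)
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Adam:
    def __init__(self, layers, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m, self.v = {}, {}
        for i, lay in enumerate(layers):
            for name, p, _ in lay.params():
                self.m[(i, name)] = np.zeros_like(p)
                self.v[(i, name)] = np.zeros_like(p)

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, lay in enumerate(self.layers):
            for name, p, gname in lay.params():
                g = getattr(lay, gname)
                m = self.m[(i, name)]
                v = self.v[(i, name)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ConvNet1D:
    """Configurable small 1-D CNN binary classifier.

    Parameters
    ----------
    conv_filters : filters per conv block (each block: conv k=7, ReLU,
        max-pool 3).
    dense_units : width of the fully connected ReLU layer before the
        sigmoid output.
    """

    def __init__(self, conv_filters=(16, 32, 64), kernel_size=7,
                 pool_size=3, dense_units=64, lr=1e-3, batch_size=32,
                 max_epochs=100, patience=10, seed=0):
        self.conv_filters = tuple(conv_filters)
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dense_units = dense_units
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _build(self, n_features, rng):
        layers = []
        c_in = 1
        length = n_features
        for c_out in self.conv_filters:
            layers.append(_Conv1D(c_in, c_out, self.kernel_size, rng))
            layers.append(_ReLU())
            layers.append(_MaxPool(self.pool_size))
            length = (length - self.kernel_size + 1) // self.pool_size
            if length < 1:
                raise ValueError("input too short for the conv stack")
            c_in = c_out
        layers.append(_GlobalAvgPool())
        layers.append(_Dense(c_in, self.dense_units, rng))
        layers.append(_ReLU())
        layers.append(_Dense(self.dense_units, 1, rng))
        self.layers = layers

    def _forward(self, X):
        h = X[:, None, :].astype(F32)
        for lay in self.layers:
            h = lay.forward(h)
        return h[:, 0]                          # logits

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=F32)
        y = np.asarray(y, dtype=F32)
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)
        opt = _Adam(self.layers, lr=self.lr)
        monitor = X_val is not None and len(X_val) > 0
        if monitor:
            X_val = np.asarray(X_val, dtype=F32)
            y_val = np.asarray(y_val, dtype=F32)
        best_acc, best_state, since_best = -1.0, None, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            idx = rng.permutation(len(X))
            for lo in range(0, len(X), self.batch_size):
                sel = idx[lo:lo + self.batch_size]
                z = self._forward(X[sel])
                p = _sigmoid(z)
                dz = ((p - y[sel]) / len(sel)).astype(F32)
                grad = dz[:, None]
                for lay in reversed(self.layers):
                    grad = lay.backward(grad)
                opt.step()
            if monitor:
                acc = float(np.mean(self.predict(X_val) == y_val))
                self.history_.append(acc)
                if acc > best_acc:
                    best_acc = acc
                    best_state = [(np.copy(p)) for lay in self.layers
                                  for _, p, _ in lay.params()]
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if monitor and best_state is not None:
            it = iter(best_state)
            for lay in self.layers:
                for _, p, _ in lay.params():
                    np.copyto(p, next(it))
            self.best_val_accuracy_ = best_acc
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=F32)
        out = np.empty(len(X))
        for lo in range(0, len(X), 256):
            out[lo:lo + 256] = _sigmoid(self._forward(X[lo:lo + 256]))
        return out

    def predict(self, X):
        # ties (p == 0.5) resolve to class 0
        return (self.predict_proba(X) > 0.5).astype(int)
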