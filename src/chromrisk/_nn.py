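"""A small residual convolutional network for DNA windows, in pure NumPy.

Architecture: one-hot input -> stem conv/BN/ReLU -> residual blocks
(conv-BN-ReLU-conv-BN + identity skip, ReLU) -> global max pool over
positions -> dense logit.  Trained with Adam on binary cross-entropy.
Forward/backward passes are written out explicitly; convolutions are im2col
matmuls so the heavy lifting stays in BLAS.

All randomness flows through a single seeded Generator, so training is
bit-reproducible for a fixed (seed, config, data) triple.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)


class Conv1D:
    """Same-padding 1-D convolution over (batch, length, channels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.W = _he_init(rng, (kernel * c_in, c_out), kernel * c_in)
        self.b = np.zeros(c_out)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (B, L, k, C): window j at position i reads xp[:, i + j, :]
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # sliding_window_view gives (B, L, C, k); put k before C
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        cols = self._im2col(x)                       # (B, L, k, C)
        self._cols = cols.reshape(B * L, self.k * self.c_in)
        self._shape = (B, L)
        y = self._cols @ self.W + self.b
        return y.reshape(B, L, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L = self._shape
        dy2 = dy.reshape(B * L, self.c_out)
        self.dW = self._cols.T @ dy2
        self.db = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(B, L, self.k, self.c_in)
        pad = self.k // 2
        dxp = np.zeros((B, L + 2 * pad, self.c_in))
        for j in range(self.k):
            dxp[:, j:j + L, :] += dcols[:, :, j, :]
        return dxp[:, pad:pad + L, :]

    @property
    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm:
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            self._std = np.sqrt(var + _EPS)
            self._xhat = (x - mean) / self._std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + _EPS)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0] * dy.shape[1]
        self.dgamma = (dy * self._xhat).sum(axis=(0, 1))
        self.dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        return (dxhat - dxhat.mean(axis=(0, 1))
                - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1))) / self._std


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class _Block:
    """conv-BN-ReLU-conv-BN + identity, then ReLU."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1D(channels, channels, kernel, rng)
        self.bn1 = BatchNorm(channels)
        self.conv2 = Conv1D(channels, channels, kernel, rng)
        self.bn2 = BatchNorm(channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x), train)
        self._mask1 = h > 0
        h = self.bn2.forward(self.conv2.forward(h * self._mask1), train)
        out = h + x
        self._mask_out = out > 0
        return out * self._mask_out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask_out
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = dh * self._mask1
        dh = self.bn1.backward(dh)
        return self.conv1.backward(dh) + dy


class ResidualNet:
    def __init__(self, n_blocks: int, n_filters: int, kernel: int, seed: int):
        rng = np.random.default_rng(seed)
        self.stem = Conv1D(4, n_filters, kernel, rng)
        self.bn0 = BatchNorm(n_filters)
        self.blocks = [_Block(n_filters, kernel, rng) for _ in range(n_blocks)]
        self.head = Dense(n_filters, 1, rng)

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.bn0.forward(self.stem.forward(x), train)
        self._mask0 = h > 0
        h = h * self._mask0
        for block in self.blocks:
            h = block.forward(h, train)
        self._argmax = h.argmax(axis=1)            # (B, F)
        self._pool_shape = h.shape
        pooled = np.take_along_axis(h, self._argmax[:, None, :], axis=1)[:, 0, :]
        return self.head.forward(pooled)[:, 0]     # logits

    def backward(self, dlogit: np.ndarray) -> None:
        dpooled = self.head.backward(dlogit[:, None])
        dh = np.zeros(self._pool_shape)
        np.put_along_axis(dh, self._argmax[:, None, :], dpooled[:, None, :], axis=1)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        dh = dh * self._mask0
        dh = self.bn0.backward(dh)
        self.stem.backward(dh)

    # -- parameters ---------------------------------------------------------
    def _layers(self):
        yield self.stem
        yield self.bn0
        for b in self.blocks:
            yield from (b.conv1, b.bn1, b.conv2, b.bn2)
        yield self.head

    def parameters(self):
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                yield layer, "gamma", "dgamma"
                yield layer, "beta", "dbeta"
            else:
                yield layer, "W", "dW"
                yield layer, "b", "db"

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._layers()):
            if isinstance(layer, BatchNorm):
                for name in ("gamma", "beta", "running_mean", "running_var"):
                    state[f"{i}.{name}"] = getattr(layer, name)
            else:
                state[f"{i}.W"] = layer.W
                state[f"{i}.b"] = layer.b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            if isinstance(layer, BatchNorm):
                for name in ("gamma", "beta", "running_mean", "running_var"):
                    setattr(layer, name, np.array(state[f"{i}.{name}"]))
            else:
                layer.W = np.array(state[f"{i}.W"])
                layer.b = np.array(state[f"{i}.b"])

    # -- training -----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            lr: float, seed: int) -> list[float]:
        """Adam on BCE-with-logits; returns per-epoch mean losses."""
        rng = np.random.default_rng(seed)
        slots = [(layer, p, g) for layer, p, g in self.parameters()]
        m = [np.zeros_like(getattr(layer, p)) for layer, p, _ in slots]
        v = [np.zeros_like(getattr(layer, p)) for layer, p, _ in slots]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        losses = []
        n = len(y)
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self.forward(xb, train=True)
                p = 1.0 / (1.0 + np.exp(-logits))
                epoch_loss += float(
                    -(yb * np.log(p + 1e-12)
                      + (1 - yb) * np.log(1 - p + 1e-12)).sum())
                self.backward((p - yb) / len(yb))
                step += 1
                for s, (layer, pname, gname) in enumerate(slots):
                    grad = getattr(layer, gname)
                    m[s] = beta1 * m[s] + (1 - beta1) * grad
                    v[s] = beta2 * v[s] + (1 - beta2) * grad * grad
                    mhat = m[s] / (1 - beta1 ** step)
                    vhat = v[s] / (1 - beta2 ** step)
                    param = getattr(layer, pname)
                    setattr(layer, pname,
                            param - lr * mhat / (np.sqrt(vhat) + eps))
            losses.append(epoch_loss / n)
        return losses

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(x))
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo:lo + batch_size], train=False)
            out[lo:lo + len(logits)] = 1.0 / (1.0 + np.exp(-logits))
        return out
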