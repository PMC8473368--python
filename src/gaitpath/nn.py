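"""A compact NumPy neural-network stack.

Implements exactly the pieces the gait classifier needs — 3x3 "same"
convolutions (im2col), 2x2 max pooling, dense layers, dropout, LSTM with
backpropagation through time, softmax cross-entropy and the Nadam
optimizer (Adam with Nesterov momentum) — with explicit forward/backward
passes on float32 arrays.  Image tensors are laid out (N, H, W, C);
sequence tensors (N, T, D).

Every layer owns :class:`Param` objects; setting ``param.trainable =
False`` freezes it (the optimizer skips it), which is how pretrained-style
block freezing is expressed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError


class Param:
    """A trainable tensor with a lazily allocated gradient accumulator."""

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self._grad: np.ndarray | None = None
        self.trainable = trainable
        self.name = name

    @property
    def grad(self) -> np.ndarray:
        if self._grad is None:
            self._grad = np.zeros_like(self.value)
        return self._grad

    @grad.setter
    def grad(self, value: np.ndarray) -> None:
        self._grad = value


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    # He-uniform: U(-sqrt(6/fan_in), +sqrt(6/fan_in))
    lim = np.float32(np.sqrt(6.0 / fan_in))
    out = rng.random(size=shape, dtype=np.float32)
    out *= 2 * lim
    out -= lim
    return out


def _glorot_init(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.float32(np.sqrt(6.0 / (fan_in + fan_out)))
    out = rng.random(size=shape, dtype=np.float32)
    out *= 2 * lim
    out -= lim
    return out


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 stride-1 'same' convolution over (N, H, W, C)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = ""):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_he_init(rng, (9 * c_in, c_out), 9 * c_in), name=f"{name}.W")
        self.b = Param(np.zeros(c_out, np.float32), name=f"{name}.b")

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((n, h, w, 3, 3, c), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + w, :]
        return cols.reshape(n * h * w, 9 * c)

    def forward(self, x, train=False):
        self._shape = x.shape
        self._cols = self._im2col(x.astype(np.float32))
        out = self._cols @ self.W.value + self.b.value
        n, h, w, _ = x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, c = self._shape
        dmat = dout.reshape(n * h * w, self.c_out)
        self.W.grad += self._cols.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 stride-2 max pooling (input H, W assumed even)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        self._shape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dout):
        n, h, w, c = self._shape
        dr = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dr, self._arg[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dr = dr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dr.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False, name: str = ""):
        if zero_init:
            w = np.zeros((d_in, d_out), np.float32)
        else:
            w = _he_init(rng, (d_in, d_out), d_in)
        self.W = Param(w, name=f"{name}.W")
        self.b = Param(np.zeros(d_out, np.float32), name=f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x.astype(np.float32)
        return self._x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class LSTMLast(Layer):
    """LSTM over (N, T, D) returning the final hidden state (N, H).

    Gate order in the packed weight matrices is (input, forget, cell,
    output); forget-gate bias starts at 1.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, name: str = ""):
        self.d_in, self.units = d_in, units
        self.Wx = Param(_glorot_init(rng, (d_in, 4 * units), d_in, units), name=f"{name}.Wx")
        self.Wh = Param(_glorot_init(rng, (units, 4 * units), units, units), name=f"{name}.Wh")
        b = np.zeros(4 * units, np.float32)
        b[units : 2 * units] = 1.0
        self.b = Param(b, name=f"{name}.b")

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        n, t, d = x.shape
        u = self.units
        self._x = x.astype(np.float32)
        h = np.zeros((n, u), np.float32)
        c = np.zeros((n, u), np.float32)
        self._cache = []
        for k in range(t):
            z = self._x[:, k, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last):
        n, t, d = self._x.shape
        u = self.units
        dx = np.zeros_like(self._x)
        dh = dh_last.astype(np.float32)
        dc = np.zeros((n, u), np.float32)
        for k in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[k]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            ).astype(np.float32)
            self.Wx.grad += self._x[:, k, :].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, k, :] = dz @ self.Wx.value.T
            dh = dz @ self.Wh.value.T
            dc = dc * f
        return dx


class BiLSTMLast(Layer):
    """Bidirectional LSTM: concatenated final hidden states of both reads.

    The forward LSTM reads steps 1..T, the backward LSTM T..1; the output
    is ``[h_fwd_T, h_bwd_T]`` of length ``2 * units``.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, name: str = "bilstm"):
        self.fwd = LSTMLast(d_in, units, rng, name=f"{name}.fwd")
        self.bwd = LSTMLast(d_in, units, rng, name=f"{name}.bwd")
        self.units = units

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, train=False):
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1, :], train)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dout):
        u = self.units
        dxf = self.fwd.backward(dout[:, :u])
        dxb = self.bwd.backward(dout[:, u:])
        return dxf + dxb[:, ::-1, :]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Nadam:
    """Adam with Nesterov momentum (Nadam update rule)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** (t + 1))
            v_hat = v / (1 - b2**t)
            update = (b1 * m_hat + (1 - b1) * g / (1 - b1**t)) / (np.sqrt(v_hat) + self.eps)
            p.value -= self.lr * update


def fit_classifier(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    params: list[Param] | None = None,
) -> dict:
    """Minibatch Nadam training of ``model`` under softmax cross-entropy.

    Returns per-epoch mean loss and training accuracy histories.
    """
    if len(x) == 0:
        raise TrainingError("no training data")
    if np.unique(y).size < 2:
        raise TrainingError("training data must contain at least 2 classes")
    opt = Nadam(model.params() if params is None else params, lr=lr)
    history = {"loss": [], "accuracy": []}
    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(correct / n)
    return history
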