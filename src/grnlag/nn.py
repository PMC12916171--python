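"""Minimal feed-forward/recurrent neural-network layers on numpy.

Implements exactly what the pair classifier needs — dense, valid 2-D
convolution (im2col), non-overlapping max pooling, inverted dropout, and
SimpleRNN/GRU/LSTM recurrences with full backpropagation through time,
plus a bidirectional wrapper — together with a numerically stable
binary-cross-entropy-with-logits loss and SGD with momentum and per-epoch
exponential learning-rate decay.

Every layer caches its forward intermediates and implements an explicit
``backward``; gradients are validated against central finite differences in
the test suite.  All randomness (weight init, dropout masks, batch order)
flows through seeded ``numpy.random.Generator`` objects, so training is
reproducible bit-for-bit on a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "ReLU", "Conv2D", "MaxPool2D", "Dropout",
    "Flatten", "AddChannel", "SimpleRNN", "GRU", "LSTM", "Bidirectional",
    "Network", "bce_with_logits", "sigmoid", "SGD",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, n: int, m: int, dtype) -> np.ndarray:
    assert n == m, "orthogonal init is used for square recurrent matrices only"
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    q = q * np.sign(np.diag(r))  # fix QR sign ambiguity for reproducibility
    return q.astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(_glorot(rng, d_in, d_out, (d_in, d_out), dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class AddChannel(Layer):
    """(N, H, W) -> (N, 1, H, W): treat a 2-D feature map as one channel."""

    def forward(self, x, train=False):
        return x[:, None, :, :]

    def backward(self, dout):
        return dout[:, 0, :, :]


class Dropout(Layer):
    """Inverted dropout: identity at inference, seeded mask in training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class Conv2D(Layer):
    """Valid 2-D convolution, stride 1, square kernel, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = c_in * kernel * kernel
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_glorot(rng, fan_in, c_out, (fan_in, c_out), dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        N, C, H, Wd = x.shape
        k = self.kernel
        if H < k or Wd < k:
            raise ValueError(f"conv input {H}x{Wd} smaller than kernel {k}x{k}")
        Ho, Wo = H - k + 1, Wd - k + 1
        patches = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k) -> rows
        cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k
        )
        self._cols, self._in_shape, self._out_hw = cols, x.shape, (Ho, Wo)
        out = cols @ self.W.value + self.b.value
        return out.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        N, C, H, Wd = self._in_shape
        Ho, Wo = self._out_hw
        k = self.kernel
        rows = dout.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.c_out)
        self.W.grad += self._cols.T @ rows
        self.b.grad += rows.sum(axis=0)
        dcols = (rows @ self.W.value.T).reshape(N, Ho, Wo, C, k, k)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping pool x pool max pooling (trailing remainder cropped)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train=False):
        N, C, H, Wd = x.shape
        s = self.pool
        Hp, Wp = H // s, Wd // s
        if Hp < 1 or Wp < 1:
            raise ValueError(f"pool size {s} too large for input {H}x{Wd}")
        self._in_shape = x.shape
        xr = x[:, :, : Hp * s, : Wp * s].reshape(N, C, Hp, s, Wp, s)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Hp, Wp, s * s)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        N, C, H, Wd = self._in_shape
        s = self.pool
        Hp, Wp = H // s, Wd // s
        dxr = np.zeros((N, C, Hp, Wp, s * s), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : Hp * s, : Wp * s] = (
            dxr.reshape(N, C, Hp, Wp, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Hp * s, Wp * s)
        )
        return dx


class _RecurrentBase(Layer):
    """Shared plumbing: runs a cell over (N, T, D), returns (N, T, H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 dtype=np.float32, reverse: bool = False):
        self.d_in, self.d_hidden, self.dtype, self.reverse = d_in, d_hidden, dtype, reverse
        self._init_params(rng)

    def forward(self, x, train=False):
        if self.reverse:
            x = x[:, ::-1, :]
        hs = self._forward_seq(x)
        if self.reverse:
            hs = hs[:, ::-1, :]
        return hs

    def backward(self, dout):
        if self.reverse:
            dout = dout[:, ::-1, :]
        dx = self._backward_seq(dout)
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class SimpleRNN(_RecurrentBase):
    """h_t = tanh(x_t W + h_{t-1} U + b), full sequence returned."""

    def _init_params(self, rng):
        D, H, dt = self.d_in, self.d_hidden, self.dtype
        self.W = Param(_glorot(rng, D, H, (D, H), dt))
        self.U = Param(_orthogonal(rng, H, H, dt))
        self.b = Param(np.zeros(H, dt))

    def params(self):
        return [self.W, self.U, self.b]

    def _forward_seq(self, x):
        N, T, D = x.shape
        H = self.d_hidden
        hs = np.zeros((N, T, H), dtype=x.dtype)
        h = np.zeros((N, H), dtype=x.dtype)
        for t in range(T):
            h = np.tanh(x[:, t] @ self.W.value + h @ self.U.value + self.b.value)
            hs[:, t] = h
        self._x, self._hs = x, hs
        return hs

    def _backward_seq(self, dout):
        x, hs = self._x, self._hs
        N, T, D = x.shape
        H = self.d_hidden
        dx = np.zeros_like(x)
        dh_carry = np.zeros((N, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dout[:, t] + dh_carry
            h = hs[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((N, H), dtype=x.dtype)
            dpre = dh * (1.0 - h * h)
            self.W.grad += x[:, t].T @ dpre
            self.U.grad += h_prev.T @ dpre
            self.b.grad += dpre.sum(axis=0)
            dx[:, t] = dpre @ self.W.value.T
            dh_carry = dpre @ self.U.value.T
        return dx


class GRU(_RecurrentBase):
    """Gated recurrent unit:

    z_t = sigma(x_t Wz + h_{t-1} Uz + bz)        update gate
    r_t = sigma(x_t Wr + h_{t-1} Ur + br)        reset gate
    c_t = tanh(x_t Wc + (r_t * h_{t-1}) Uc + bc) candidate state
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t
    """

    def _init_params(self, rng):
        D, H, dt = self.d_in, self.d_hidden, self.dtype
        self.Wz = Param(_glorot(rng, D, H, (D, H), dt)); self.Uz = Param(_orthogonal(rng, H, H, dt)); self.bz = Param(np.zeros(H, dt))
        self.Wr = Param(_glorot(rng, D, H, (D, H), dt)); self.Ur = Param(_orthogonal(rng, H, H, dt)); self.br = Param(np.zeros(H, dt))
        self.Wc = Param(_glorot(rng, D, H, (D, H), dt)); self.Uc = Param(_orthogonal(rng, H, H, dt)); self.bc = Param(np.zeros(H, dt))

    def params(self):
        return [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br, self.Wc, self.Uc, self.bc]

    def _forward_seq(self, x):
        N, T, D = x.shape
        H = self.d_hidden
        hs = np.zeros((N, T, H), dtype=x.dtype)
        zs = np.zeros_like(hs); rs = np.zeros_like(hs); cs = np.zeros_like(hs)
        h = np.zeros((N, H), dtype=x.dtype)
        for t in range(T):
            xt = x[:, t]
            z = sigmoid(xt @ self.Wz.value + h @ self.Uz.value + self.bz.value)
            r = sigmoid(xt @ self.Wr.value + h @ self.Ur.value + self.br.value)
            c = np.tanh(xt @ self.Wc.value + (r * h) @ self.Uc.value + self.bc.value)
            h = (1.0 - z) * h + z * c
            hs[:, t], zs[:, t], rs[:, t], cs[:, t] = h, z, r, c
        self._x, self._hs, self._zs, self._rs, self._cs = x, hs, zs, rs, cs
        return hs

    def _backward_seq(self, dout):
        x, hs, zs, rs, cs = self._x, self._hs, self._zs, self._rs, self._cs
        N, T, D = x.shape
        H = self.d_hidden
        dx = np.zeros_like(x)
        dh_carry = np.zeros((N, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dout[:, t] + dh_carry
            z, r, c = zs[:, t], rs[:, t], cs[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((N, H), dtype=x.dtype)
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)
            dc_pre = dc * (1.0 - c * c)
            drh = dc_pre @ self.Uc.value.T
            dr = drh * h_prev
            dh_prev += drh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            xt = x[:, t]
            self.Wc.grad += xt.T @ dc_pre; self.Uc.grad += (r * h_prev).T @ dc_pre; self.bc.grad += dc_pre.sum(axis=0)
            self.Wz.grad += xt.T @ dz_pre; self.Uz.grad += h_prev.T @ dz_pre; self.bz.grad += dz_pre.sum(axis=0)
            self.Wr.grad += xt.T @ dr_pre; self.Ur.grad += h_prev.T @ dr_pre; self.br.grad += dr_pre.sum(axis=0)
            dx[:, t] = dc_pre @ self.Wc.value.T + dz_pre @ self.Wz.value.T + dr_pre @ self.Wr.value.T
            dh_carry = dh_prev + dz_pre @ self.Uz.value.T + dr_pre @ self.Ur.value.T
        return dx


class LSTM(_RecurrentBase):
    """Standard LSTM: i, f, o gates, candidate g; c_t = f*c + i*g; h_t = o*tanh(c_t)."""

    def _init_params(self, rng):
        D, H, dt = self.d_in, self.d_hidden, self.dtype
        self.W = Param(_glorot(rng, D, 4 * H, (D, 4 * H), dt))
        self.U = Param(np.concatenate([_orthogonal(rng, H, H, dt) for _ in range(4)], axis=1))
        b = np.zeros(4 * H, dt)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b = Param(b)

    def params(self):
        return [self.W, self.U, self.b]

    def _forward_seq(self, x):
        N, T, D = x.shape
        H = self.d_hidden
        hs = np.zeros((N, T, H), dtype=x.dtype)
        self._gates = np.zeros((N, T, 4 * H), dtype=x.dtype)
        self._cells = np.zeros((N, T, H), dtype=x.dtype)
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        for t in range(T):
            pre = x[:, t] @ self.W.value + h @ self.U.value + self.b.value
            i = sigmoid(pre[:, :H]); f = sigmoid(pre[:, H : 2 * H])
            o = sigmoid(pre[:, 2 * H : 3 * H]); g = np.tanh(pre[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            hs[:, t] = h
            self._gates[:, t] = np.concatenate([i, f, o, g], axis=1)
            self._cells[:, t] = c
        self._x, self._hs = x, hs
        return hs

    def _backward_seq(self, dout):
        x, hs = self._x, self._hs
        N, T, D = x.shape
        H = self.d_hidden
        dx = np.zeros_like(x)
        dh_carry = np.zeros((N, H), dtype=x.dtype)
        dc_carry = np.zeros((N, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dout[:, t] + dh_carry
            g4 = self._gates[:, t]
            i, f, o, g = g4[:, :H], g4[:, H : 2 * H], g4[:, 2 * H : 3 * H], g4[:, 3 * H :]
            c = self._cells[:, t]
            c_prev = self._cells[:, t - 1] if t > 0 else np.zeros((N, H), dtype=x.dtype)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((N, H), dtype=x.dtype)
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_carry
            di = dc * g; df = dc * c_prev; dg = dc * i
            dc_carry = dc * f
            dpre = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g * g)], axis=1
            )
            self.W.grad += x[:, t].T @ dpre
            self.U.grad += h_prev.T @ dpre
            self.b.grad += dpre.sum(axis=0)
            dx[:, t] = dpre @ self.W.value.T
            dh_carry = dpre @ self.U.value.T
        return dx


class Bidirectional(Layer):
    """Runs two independent recurrent layers (forward and reversed) and
    concatenates their per-step hidden states along the feature axis."""

    def __init__(self, cell_cls, d_in: int, d_hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.fw = cell_cls(d_in, d_hidden, rng, dtype=dtype, reverse=False)
        self.bw = cell_cls(d_in, d_hidden, rng, dtype=dtype, reverse=True)
        self.d_hidden = d_hidden

    def params(self):
        return self.fw.params() + self.bw.params()

    def forward(self, x, train=False):
        return np.concatenate([self.fw.forward(x, train), self.bw.forward(x, train)], axis=2)

    def backward(self, dout):
        H = self.d_hidden
        return self.fw.backward(dout[:, :, :H]) + self.bw.backward(dout[:, :, H:])


class Network:
    """A plain sequential stack of layers with an explicit backward pass."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    z = logits.reshape(-1).astype(np.float64)
    y = y.reshape(-1).astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.reshape(logits.shape).astype(logits.dtype)


class SGD:
    """SGD with classical momentum and exponential per-epoch lr decay."""

    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9,
                 decay: float = 0.95):
        self.params = params
        self.lr0, self.lr = lr, lr
        self.momentum = momentum
        self.decay = decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def set_epoch(self, epoch: int) -> None:
        self.lr = self.lr0 * self.decay**epoch

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
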