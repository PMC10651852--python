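"""Minimal layer zoo used by the PolyaID / PolyaStrength networks.

Every layer owns its parameters and gradient buffers and implements the pair
``forward(x, train)`` / ``backward(dout)``.  Shapes follow the channels-last
convention: sequence inputs are ``(N, L, C)``.  All arithmetic is float32;
gradients are accumulated fresh on every backward call.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class; stateless layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution, stride 1.

    Input ``(N, L, C_in)`` -> output ``(N, L - width + 1, filters)``.
    Implemented as an im2col matrix product.
    """

    def __init__(self, in_channels: int, filters: int, width: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.width = width
        self.in_channels = in_channels
        self.filters = filters
        self.params = {
            "W": glorot(rng, (width * in_channels, filters)),
            "b": np.zeros(filters, dtype=F32),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, _ = x.shape
        t = length - self.width + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        # windows: (N, T, C, width) -> (N*T, width*C) matching W's (width*C) rows
        cols = windows.transpose(0, 1, 3, 2).reshape(n * t, self.width * self.in_channels)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, t, self.filters)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, t, _ = dout.shape
        dflat = dout.reshape(n * t, self.filters)
        self.grads["W"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(n, t, self.width, self.in_channels)
        dx = np.zeros(self._in_shape, dtype=F32)
        for w in range(self.width):
            dx[:, w:w + t, :] += dcols[:, :, w, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(F32, copy=False)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pool; trailing remainder is dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.pool == 1:
            self._passthrough = True
            return x
        self._passthrough = False
        n, length, c = x.shape
        t = length // self.pool
        xr = x[:, : t * self.pool, :].reshape(n, t, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._passthrough:
            return dout
        n, t, c = dout.shape
        dx = np.zeros((n, t, self.pool, c), dtype=F32)
        ni, ti, ci = np.ogrid[:n, :t, :c]
        dx[ni, ti, self._argmax, ci] = dout
        out = np.zeros(self._in_shape, dtype=F32)
        out[:, : t * self.pool, :] = dx.reshape(n, t * self.pool, c)
        return out


class _LSTMDirection:
    """One direction of an LSTM, gate order (i, f, g, o)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        self.units = units
        self.W = glorot(rng, (in_dim, 4 * units))
        self.U = glorot(rng, (units, 4 * units))
        self.b = np.zeros(4 * units, dtype=F32)
        # forget-gate bias of 1 stabilises early training
        self.b[units: 2 * units] = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        h = np.zeros((n, self.units), dtype=F32)
        c = np.zeros((n, self.units), dtype=F32)
        self._x = x
        self._cache = []
        hs = np.empty((n, t, self.units), dtype=F32)
        xw = x.reshape(n * t, -1) @ self.W
        xw = xw.reshape(n, t, 4 * self.units)
        u = self.units
        for step in range(t):
            a = xw[:, step, :] + h @ self.U + self.b
            i = sigmoid(a[:, :u])
            f = sigmoid(a[:, u:2 * u])
            g = np.tanh(a[:, 2 * u:3 * u])
            o = sigmoid(a[:, 3 * u:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, step, :] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return hs

    def backward(self, dhs: np.ndarray):
        n, t, u = dhs.shape
        x = self._x
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, u), dtype=F32)
        dc_next = np.zeros((n, u), dtype=F32)
        da_all = np.empty((n, t, 4 * u), dtype=F32)
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[step]
            dh = dhs[:, step, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            da_all[:, step, :] = da
            dh_next = da @ self.U.T
            dU += h_prev.T @ da
        da_flat = da_all.reshape(n * t, 4 * u)
        dW = x.reshape(n * t, -1).T @ da_flat
        db = da_flat.sum(axis=0)
        dx = (da_flat @ self.W.T).reshape(x.shape)
        return dx, dW, dU, db


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full concatenated sequence (N, T, 2U)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        self.fwd = _LSTMDirection(in_dim, units, rng)
        self.bwd = _LSTMDirection(in_dim, units, rng)
        self.params = {
            "Wf": self.fwd.W, "Uf": self.fwd.U, "bf": self.fwd.b,
            "Wb": self.bwd.W, "Ub": self.bwd.U, "bb": self.bwd.b,
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        u = self.units
        dxf, dWf, dUf, dbf = self.fwd.backward(np.ascontiguousarray(dout[:, :, :u]))
        dxb, dWb, dUb, dbb = self.bwd.backward(
            np.ascontiguousarray(dout[:, ::-1, u:]))
        self.grads = {"Wf": dWf, "Uf": dUf, "bf": dbf,
                      "Wb": dWb, "Ub": dUb, "bb": dbb}
        return dxf + dxb[:, ::-1, :]


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": glorot(rng, (in_dim, out_dim)),
            "b": np.zeros(out_dim, dtype=F32),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask
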