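"""Sequence layers with explicit forward/backward passes (float32).

All layers operate on (batch, time, features) arrays; the embedding takes
(batch, time) integer inputs.  Each layer owns its parameters and the
gradients of the most recent backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Embedding", "Dense", "BiLSTM", "Dropout"]

F32 = np.float32


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity
    return q.astype(F32)


class Layer:
    """Base layer: ``params``/``grads`` are parallel name->array dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Embedding(Layer):
    """Token index -> dense vector lookup, (B,T) int -> (B,T,D)."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.vocab_size, self.dim = vocab_size, dim
        self.params["W"] = rng.uniform(-0.05, 0.05, (vocab_size, dim)).astype(F32)

    def forward(self, x, train, rng):
        self._x = x
        return self.params["W"][x]

    def backward(self, dy):
        dW = np.zeros_like(self.params["W"])
        np.add.at(dW, self._x, dy)
        self.grads["W"] = dW
        return None  # nothing upstream of the lookup


class Dense(Layer):
    """Position-wise affine map on the last axis, optional ReLU."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "relu"):
        super().__init__()
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        if out_dim <= 0:
            raise ValueError("dense width must be positive")
        self.in_dim, self.out_dim, self.activation = in_dim, out_dim, activation
        self.params["W"] = _glorot_uniform(rng, in_dim, out_dim, (in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim, dtype=F32)

    def forward(self, x, train, rng):
        self._shape = x.shape
        x2 = x.reshape(-1, self.in_dim)
        z = x2 @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            np.maximum(z, 0.0, out=z)
        self._x2, self._z = x2, z
        return z.reshape(*self._shape[:-1], self.out_dim)

    def backward(self, dy):
        dz = dy.reshape(-1, self.out_dim)
        if self.activation == "relu":
            dz = dz * (self._z > 0)
        self.grads["W"] = self._x2.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return (dz @ self.params["W"].T).reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0,1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _LSTMDirection:
    """One direction of an LSTM over a full sequence (gate order i,f,g,o)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        H = units
        self.in_dim, self.H = in_dim, H
        self.Wx = _glorot_uniform(rng, in_dim, 4 * H, (in_dim, 4 * H))
        self.Wh = np.concatenate([_orthogonal(rng, H) for _ in range(4)], axis=1)
        b = np.zeros(4 * H, dtype=F32)
        b[H:2 * H] = 1.0  # forget-gate bias opens the memory path at init
        self.b = b

    def forward(self, x):
        B, T, D = x.shape
        H = self.H
        dt = x.dtype
        pre = (x.reshape(B * T, D) @ self.Wx).reshape(B, T, 4 * H) + self.b
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        self._x, self._pre = x, pre
        self._cache = []
        out = np.empty((B, T, H), dtype=dt)
        for t in range(T):
            z = pre[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return out

    def backward(self, dout):
        x, H = self._x, self.H
        B, T, D = x.shape
        dt = x.dtype
        dWh = np.zeros_like(self.Wh, dtype=dt)
        dpre = np.empty((B, T, 4 * H), dtype=dt)
        dh = np.zeros((B, H), dtype=dt)
        dc = np.zeros((B, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = dh + dout[:, t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = np.empty((B, 4 * H), dtype=dt)
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            dWh += h_prev.T @ dz
            dh = dz @ self.Wh.T
            dc = dc * f
            dpre[:, t] = dz
        dpre2 = dpre.reshape(B * T, 4 * H)
        self.dWx = x.reshape(B * T, D).T @ dpre2
        self.dWh = dWh
        self.db = dpre2.sum(axis=0)
        self._cache = None
        return (dpre2 @ self.Wx.T).reshape(B, T, D)


def _sigmoid(z):
    # numerically safe logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BiLSTM(Layer):
    """Bidirectional LSTM returning full sequences, (B,T,D) -> (B,T,2H)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        if units <= 0:
            raise ValueError("LSTM units must be positive")
        self.units = units
        self.fwd = _LSTMDirection(in_dim, units, rng)
        self.bwd = _LSTMDirection(in_dim, units, rng)
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            self.params[f"{tag}_Wx"] = d.Wx
            self.params[f"{tag}_Wh"] = d.Wh
            self.params[f"{tag}_b"] = d.b

    def forward(self, x, train, rng):
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        H = self.units
        dxf = self.fwd.backward(np.ascontiguousarray(dy[..., :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))[:, ::-1]
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            self.grads[f"{tag}_Wx"] = d.dWx
            self.grads[f"{tag}_Wh"] = d.dWh
            self.grads[f"{tag}_b"] = d.db
        return dxf + dxb
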