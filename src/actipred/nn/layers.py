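"""Dense, convolutional and recurrent layers with explicit backpropagation.

Shapes follow the (batch, time, feature) convention.  Each layer caches what
its backward pass needs during ``forward``; calling ``backward`` consumes the
cache of the most recent forward call.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


from scipy.special import expit as _sigmoid


class Layer:
    def parameters(self) -> list[Parameter]:
        return list(self._params)

    def __init__(self):
        self._params: list[Parameter] = []

    def _add(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(name, value)
        self._params.append(p)
        return p


class Dense(Layer):
    """Affine map on the last axis, optionally followed by relu/tanh."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None, name: str = "dense"):
        super().__init__()
        self.activation = activation
        self.W = self._add(f"{name}.W", glorot_uniform(rng, (in_dim, out_dim)))
        self.b = self._add(f"{name}.b", np.zeros(out_dim))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            z = np.maximum(z, 0.0)
        elif self.activation == "tanh":
            z = np.tanh(z)
        self._y = z
        return z

    def forward_static(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without caching (inference loops)."""
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            z = np.maximum(z, 0.0)
        elif self.activation == "tanh":
            z = np.tanh(z)
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dy = dy * (self._y > 0)
        elif self.activation == "tanh":
            dy = dy * (1.0 - self._y**2)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return (dy2 @ self.W.value.T).reshape(self._x.shape)


class Conv1D(Layer):
    """1-D convolution over time with 'same' padding (stride 1).

    For kernel size k the input is padded (k-1)//2 on the left and k//2 on
    the right so output length equals input length.
    """

    def __init__(self, in_dim: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, activation: str | None = "relu",
                 name: str = "conv"):
        super().__init__()
        self.k = int(kernel_size)
        self.activation = activation
        scale = np.sqrt(6.0 / (self.k * in_dim + filters))
        self.W = self._add(
            f"{name}.W", rng.uniform(-scale, scale, size=(self.k, in_dim, filters))
        )
        self.b = self._add(f"{name}.b", np.zeros(filters))

    def _pads(self) -> tuple[int, int]:
        return (self.k - 1) // 2, self.k // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pl, pr = self._pads()
        T = x.shape[1]
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        y = np.broadcast_to(self.b.value, (x.shape[0], T, self.W.value.shape[2])).copy()
        for j in range(self.k):
            y += xp[:, j : j + T] @ self.W.value[j]
        self._xp, self._T = xp, T
        if self.activation == "relu":
            y = np.maximum(y, 0.0)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dy = dy * (self._y > 0)
        xp, T = self._xp, self._T
        self.b.grad += dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            self.W.grad[j] += np.einsum("btd,bto->do", xp[:, j : j + T], dy)
            dxp[:, j : j + T] += dy @ self.W.value[j].T
        pl, _ = self._pads()
        return dxp[:, pl : pl + T]


class LSTM(Layer):
    """Single LSTM layer returning the full hidden-state sequence.

    Standard cell with input, forget and output gates and candidate update:
    c_t = f_t*c_{t-1} + i_t*g_t, h_t = o_t*tanh(c_t).  Gate preactivations
    are ordered [i, f, g, o].  The forget-gate bias starts at 1 so early
    training does not wash out the cell state.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 name: str = "lstm"):
        super().__init__()
        self.units = H = int(units)
        self.in_dim = in_dim
        self.W = self._add(f"{name}.W", glorot_uniform(rng, (in_dim, 4 * H)))
        U = np.concatenate([orthogonal(rng, H) for _ in range(4)], axis=1)
        self.U = self._add(f"{name}.U", U)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.b = self._add(f"{name}.b", b)

    def forward(self, x: np.ndarray, train: bool = False,
                h0: np.ndarray | None = None, c0: np.ndarray | None = None) -> np.ndarray:
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H)) if h0 is None else h0
        c = np.zeros((B, H)) if c0 is None else c0
        Zx = x.reshape(B * T, -1) @ self.W.value
        Zx = Zx.reshape(B, T, 4 * H) + self.b.value
        I = np.empty((B, T, H)); F = np.empty((B, T, H))
        G = np.empty((B, T, H)); O = np.empty((B, T, H))
        TC = np.empty((B, T, H)); Cprev = np.empty((B, T, H))
        Hprev = np.empty((B, T, H)); Hseq = np.empty((B, T, H))
        U = self.U.value
        for t in range(T):
            Hprev[:, t] = h
            Cprev[:, t] = c
            a = Zx[:, t] + h @ U
            i = _sigmoid(a[:, :H]); f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H]); o = _sigmoid(a[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, t], F[:, t], G[:, t], O[:, t], TC[:, t] = i, f, g, o, tc
            Hseq[:, t] = h
        self._cache = (x, I, F, G, O, TC, Cprev, Hprev)
        self.h_last, self.c_last = h, c
        self.dh0 = self.dc0 = None
        return Hseq

    def step(self, x_t: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One inference step (no caching): returns (h_new, c_new)."""
        H = self.units
        a = x_t @ self.W.value + h @ self.U.value + self.b.value
        i = _sigmoid(a[:, :H]); f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H]); o = _sigmoid(a[:, 3 * H :])
        c_new = f * c + i * g
        return o * np.tanh(c_new), c_new

    def backward(self, dHseq: np.ndarray | None,
                 dh_last: np.ndarray | None = None,
                 dc_last: np.ndarray | None = None) -> np.ndarray:
        x, I, F, G, O, TC, Cprev, Hprev = self._cache
        B, T, H = I.shape
        dh = np.zeros((B, H)) if dh_last is None else dh_last.copy()
        dc = np.zeros((B, H)) if dc_last is None else dc_last.copy()
        dA = np.empty((B, T, 4 * H))
        U = self.U.value
        for t in range(T - 1, -1, -1):
            if dHseq is not None:
                dh = dh + dHseq[:, t]
            i, f, g, o, tc, cp = I[:, t], F[:, t], G[:, t], O[:, t], TC[:, t], Cprev[:, t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * cp
            da = dA[:, t]
            da[:, :H] = di * i * (1.0 - i)
            da[:, H : 2 * H] = df * f * (1.0 - f)
            da[:, 2 * H : 3 * H] = dg * (1.0 - g**2)
            da[:, 3 * H :] = do * o * (1.0 - o)
            dc = dc * f
            dh = da @ U.T
        self.dh0, self.dc0 = dh, dc
        x2 = x.reshape(B * T, -1)
        dA2 = dA.reshape(B * T, 4 * H)
        self.W.grad += x2.T @ dA2
        self.b.grad += dA2.sum(axis=0)
        self.U.grad += np.einsum("bth,btk->hk", Hprev, dA)
        return (dA2 @ self.W.value.T).reshape(x.shape)


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and time-reversed passes concatenated.

    With ``return_sequences`` the per-step outputs are concatenated (width
    2*units); otherwise the two final hidden states are concatenated.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True, name: str = "bilstm"):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.fw = LSTM(in_dim, units, rng, name=f"{name}.fw")
        self.bw = LSTM(in_dim, units, rng, name=f"{name}.bw")
        self._params = self.fw._params + self.bw._params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fw_seq = self.fw.forward(x, train)
        bw_seq = self.bw.forward(x[:, ::-1], train)
        if self.return_sequences:
            return np.concatenate([fw_seq, bw_seq[:, ::-1]], axis=-1)
        return np.concatenate([self.fw.h_last, self.bw.h_last], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.units
        if self.return_sequences:
            dx_f = self.fw.backward(dy[..., :H])
            dx_b = self.bw.backward(dy[..., H:][:, ::-1])
        else:
            dx_f = self.fw.backward(None, dh_last=dy[:, :H])
            dx_b = self.bw.backward(None, dh_last=dy[:, H:])
        return dx_f + dx_b[:, ::-1]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout requires an rng during training")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask
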