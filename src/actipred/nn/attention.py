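"""Sinusoidal positional encoding and (multi-head) scaled dot-product attention.

The positional-encoding matrix interleaves sines and cosines whose
wavelengths form a geometric progression from 2*pi to 10000*2*pi, giving each
time step a unique, translation-structured signature that is simply added to
the embedded signal.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, glorot_uniform

_NEG_INF = -1e30


def positional_encoding(max_len: int, d_mod: int, base: float = 10000.0) -> np.ndarray:
    """Return the (max_len, d_mod) sine/cosine position matrix.

    Entry (pos, 2i) = sin(pos / base^(2i/d_mod)) and entry (pos, 2i+1) =
    cos(pos / base^(2i/d_mod)); all values lie in [-1, 1].
    """
    if d_mod % 2:
        raise ValueError("d_mod must be even")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_mod // 2)[None, :]
    angle = pos / base ** (2.0 * i / d_mod)
    pe = np.empty((max_len, d_mod))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _softmax_last(x: np.ndarray) -> np.ndarray:
    # operates in place on a freshly produced score array
    x -= x.max(axis=-1, keepdims=True)
    np.exp(x, out=x)
    x /= x.sum(axis=-1, keepdims=True)
    return x


def scaled_dot_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """softmax(Q K^T / sqrt(d_k)) V, broadcasting over leading batch axes.

    ``mask`` (optional, broadcastable to the score shape) holds additive
    logits, e.g. large negative values to forbid attending to a position.
    The weight matrix is row-stochastic.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must share the sequence dimension")
    d_k = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        scores = scores + mask
    weights = _softmax_last(scores)
    out = weights @ V
    return (out, weights) if return_weights else out


def causal_mask(n: int) -> np.ndarray:
    """Additive mask forbidding attention to strictly future positions."""
    return np.triu(np.full((n, n), _NEG_INF), k=1)


class MultiHeadAttention(Layer):
    """Self-attention over a (batch, time, width) sequence in ``n_heads`` heads.

    Learned projections map the input to per-head queries, keys and values;
    the heads' scaled dot-product outputs are concatenated and linearly
    re-projected to the input width.  With ``causal=True`` each position may
    attend only to itself and earlier positions, so training-time attention
    equals what incremental autoregressive decoding computes.
    """

    def __init__(self, width: int, n_heads: int, rng: np.random.Generator,
                 causal: bool = False, fast: bool = False, name: str = "mha"):
        super().__init__()
        if width % n_heads:
            raise ValueError(f"width {width} not divisible by n_heads {n_heads}")
        self.width = width
        self.n_heads = n_heads
        self.d_k = width // n_heads
        self.causal = causal
        # fast mode runs the O(T^2) score/weight arithmetic in float32;
        # parameters and projections stay float64
        self.fast = fast
        self.Wq = self._add(f"{name}.Wq", glorot_uniform(rng, (width, width)))
        self.Wk = self._add(f"{name}.Wk", glorot_uniform(rng, (width, width)))
        self.Wv = self._add(f"{name}.Wv", glorot_uniform(rng, (width, width)))
        self.Wo = self._add(f"{name}.Wo", glorot_uniform(rng, (width, width)))

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, D = x.shape
        dt = np.float32 if self.fast else x.dtype
        q = self._split((x @ self.Wq.value).astype(dt, copy=False))
        k = self._split((x @ self.Wk.value).astype(dt, copy=False))
        v = self._split((x @ self.Wv.value).astype(dt, copy=False))
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(self.d_k).astype(dt)
        if self.causal:
            scores = scores + causal_mask(T).astype(dt)
        A = _softmax_last(scores)
        heads = A @ v
        concat = self._merge(heads).astype(x.dtype, copy=False)
        self._cache = (x, q, k, v, A, concat)
        return concat @ self.Wo.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, q, k, v, A, concat = self._cache
        B, T, D = x.shape
        dt = q.dtype
        d2 = dy.reshape(-1, D)
        self.Wo.grad += concat.reshape(-1, D).T @ d2
        dconcat = self._split((dy @ self.Wo.value.T).astype(dt, copy=False))
        dA = dconcat @ np.swapaxes(v, -1, -2)
        dv = np.swapaxes(A, -1, -2) @ dconcat
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.d_k).astype(dt)
        dq = dscores @ k
        dk = np.swapaxes(dscores, -1, -2) @ q
        dqm = self._merge(dq).astype(x.dtype, copy=False)
        dkm = self._merge(dk).astype(x.dtype, copy=False)
        dvm = self._merge(dv).astype(x.dtype, copy=False)
        x2 = x.reshape(-1, D)
        self.Wq.grad += x2.T @ dqm.reshape(-1, D)
        self.Wk.grad += x2.T @ dkm.reshape(-1, D)
        self.Wv.grad += x2.T @ dvm.reshape(-1, D)
        return (
            dqm @ self.Wq.value.T + dkm @ self.Wk.value.T + dvm @ self.Wv.value.T
        )

    # -- incremental (autoregressive) interface -------------------------------
    def init_cache(self) -> dict:
        return {"k": None, "v": None}

    def step(self, x_t: np.ndarray, cache: dict) -> np.ndarray:
        """Attend from the newest position over all positions seen so far.

        ``x_t`` has shape (batch, width).  Equals column t of the causal
        forward pass when called sequentially.
        """
        B = x_t.shape[0]
        q = x_t @ self.Wq.value
        k_new = (x_t @ self.Wk.value).reshape(B, self.n_heads, 1, self.d_k)
        v_new = (x_t @ self.Wv.value).reshape(B, self.n_heads, 1, self.d_k)
        if cache["k"] is None:
            cache["k"], cache["v"] = k_new, v_new
        else:
            cache["k"] = np.concatenate([cache["k"], k_new], axis=2)
            cache["v"] = np.concatenate([cache["v"], v_new], axis=2)
        qh = q.reshape(B, self.n_heads, 1, self.d_k)
        scores = qh @ np.swapaxes(cache["k"], -1, -2) / np.sqrt(self.d_k)
        A = _softmax_last(scores)
        out = (A @ cache["v"]).reshape(B, self.width)
        return out @ self.Wo.value
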