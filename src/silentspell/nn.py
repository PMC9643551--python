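"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly what the decoding models need: a 1-D temporal
convolution, gated recurrent units (single direction and bidirectional),
LSTM cells with carried state for truncated backpropagation through time,
dense layers, dropout, softmax cross-entropy, and Adam.  All layers
propagate gradients to their inputs, which the analysis module uses for
gradient-based electrode attribution.

Shapes are batch-first: sequences are (batch, time, features).  All
randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "ReLU",
    "Dropout",
    "GRU",
    "BiGRU",
    "LSTM",
    "Dense",
    "Adam",
    "softmax",
    "softmax_xent",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) > 1 else 1, shape[-1]
    if len(shape) == 3:  # conv kernel (k, in, out)
        fan_in = shape[0] * shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the leading axes; returns (loss, dlogits, probs).

    ``labels`` are integer class ids broadcast over all but the last axis.
    """
    p = softmax(logits)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_y = labels.reshape(-1)
    n = flat_y.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(flat_p[np.arange(n), flat_y] + eps))
    d = flat_p.copy()
    d[np.arange(n), flat_y] -= 1.0
    d /= n
    return float(loss), d.reshape(logits.shape), p


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Conv1D:
    """Temporal convolution over (batch, time, features) with stride."""

    def __init__(self, n_in: int, n_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel = kernel
        self.stride = stride
        self.W = Param(_glorot(rng, (kernel, n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_len(self, t: int) -> int:
        return (t - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        b, t, f = x.shape
        to = self.out_len(t)
        xw = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        # xw: (batch, to, features, kernel)
        y = np.einsum("btfk,kfo->bto", xw[:, :to], self.W.value) + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        b, t, f = x.shape
        to = dy.shape[1]
        xw = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        self.W.grad += np.einsum("btfk,bto->kfo", xw[:, :to], dy)
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dx = np.zeros_like(x)
        for j in range(self.kernel):
            dx[:, j : j + to * self.stride : self.stride] += dy @ self.W.value[j].T
        return dx


class GRU:
    """Single-direction GRU over full sequences, returning all hidden states.

    Gate layout [update z, reset r, candidate n]; the reset gate multiplies
    the recurrent contribution of the candidate:
    ``n = tanh(W_n x + b_n + r * (U_n h))``, ``h' = (1 - z) * n + z * h``.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.h = n_hidden
        self.W = Param(_glorot(rng, (n_in, 3 * n_hidden)))
        self.U = Param(_glorot(rng, (n_hidden, 3 * n_hidden)))
        self.b = Param(np.zeros(3 * n_hidden))
        self._cache: dict | None = None

    def params(self) -> list[Param]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        hdim = self.h
        gx = x @ self.W.value + self.b.value  # (b, t, 3h)
        h = np.zeros((b, hdim))
        hs = np.empty((t, b, hdim))
        zs = np.empty((t, b, hdim))
        rs = np.empty((t, b, hdim))
        ns = np.empty((t, b, hdim))
        ghn = np.empty((t, b, hdim))
        hprev = np.empty((t, b, hdim))
        U = self.U.value
        for ti in range(t):
            gh = h @ U  # (b, 3h)
            z = sigmoid(gx[:, ti, :hdim] + gh[:, :hdim])
            r = sigmoid(gx[:, ti, hdim : 2 * hdim] + gh[:, hdim : 2 * hdim])
            gn = gh[:, 2 * hdim :]
            n = np.tanh(gx[:, ti, 2 * hdim :] + r * gn)
            hprev[ti] = h
            h = (1.0 - z) * n + z * h
            hs[ti], zs[ti], rs[ti], ns[ti], ghn[ti] = h, z, r, n, gn
        self._cache = {"x": x, "hs": hs, "zs": zs, "rs": rs, "ns": ns, "ghn": ghn, "hprev": hprev}
        return np.transpose(hs, (1, 0, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._cache
        x = c["x"]
        b, t, _ = x.shape
        hdim = self.h
        U = self.U.value
        W = self.W.value
        dgx = np.zeros((b, t, 3 * hdim))
        dU = np.zeros_like(U)
        dh = np.zeros((b, hdim))
        dout_t = np.transpose(dout, (1, 0, 2))
        for ti in range(t - 1, -1, -1):
            dh = dh + dout_t[ti]
            z, r, n, gn, hp = c["zs"][ti], c["rs"][ti], c["ns"][ti], c["ghn"][ti], c["hprev"][ti]
            dn = dh * (1.0 - z)
            dz = dh * (hp - n)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)
            dr = dan * gn
            dgn = dan * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dgx[:, ti, :hdim] = daz
            dgx[:, ti, hdim : 2 * hdim] = dar
            dgx[:, ti, 2 * hdim :] = dan
            dgh = np.concatenate([daz, dar, dgn], axis=1)  # grad wrt h_prev @ U
            dU += hp.T @ dgh
            dh = dh_prev + dgh @ U.T
        self.W.grad += np.tensordot(x, dgx, axes=((0, 1), (0, 1)))
        self.U.grad += dU
        self.b.grad += dgx.reshape(-1, 3 * hdim).sum(axis=0)
        return dgx @ W.T


class BiGRU:
    """Bidirectional GRU: concatenated forward and time-reversed outputs."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fwd = GRU(n_in, n_hidden, rng)
        self.bwd = GRU(n_in, n_hidden, rng)
        self.h = n_hidden

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = self.h
        dxf = self.fwd.backward(dy[:, :, :h])
        dxb = self.bwd.backward(dy[:, ::-1, h:])[:, ::-1]
        return dxf + dxb


class LSTM:
    """LSTM over sequences with optional carried state (for TBPTT).

    Gate layout [input i, forget f, cell g, output o].
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.h = n_hidden
        self.W = Param(_glorot(rng, (n_in, 4 * n_hidden)))
        self.U = Param(_glorot(rng, (n_hidden, 4 * n_hidden)))
        self.b = Param(np.zeros(4 * n_hidden))
        # forget-gate bias of 1 stabilizes early training
        self.b.value[n_hidden : 2 * n_hidden] = 1.0
        self._cache: dict | None = None

    def params(self) -> list[Param]:
        return [self.W, self.U, self.b]

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        state: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> np.ndarray:
        b, t, _ = x.shape
        hd = self.h
        if state is None:
            h = np.zeros((b, hd))
            cc = np.zeros((b, hd))
        else:
            h, cc = state
        gx = x @ self.W.value + self.b.value
        U = self.U.value
        caches = []
        hs = np.empty((b, t, hd))
        for ti in range(t):
            a = gx[:, ti] + h @ U
            i = sigmoid(a[:, :hd])
            f = sigmoid(a[:, hd : 2 * hd])
            g = np.tanh(a[:, 2 * hd : 3 * hd])
            o = sigmoid(a[:, 3 * hd :])
            c_new = f * cc + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((h, cc, i, f, g, o, tanh_c))
            h, cc = h_new, c_new
            hs[:, ti] = h
        self._cache = {"x": x, "caches": caches}
        self.state = (h, cc)  # carried (detached) state for TBPTT
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._cache
        x = c["x"]
        b, t, _ = x.shape
        hd = self.h
        U = self.U.value
        da_all = np.zeros((b, t, 4 * hd))
        dU = np.zeros_like(U)
        dh = np.zeros((b, hd))
        dc = np.zeros((b, hd))
        for ti in range(t - 1, -1, -1):
            hp, cp, i, f, g, o, tanh_c = c["caches"][ti]
            dh = dh + dout[:, ti]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
            di = dc * g
            df = dc * cp
            dg = dc * i
            dc = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            da_all[:, ti] = da
            dU += hp.T @ da
            dh = da @ U.T
        self.W.grad += np.tensordot(x, da_all, axes=((0, 1), (0, 1)))
        self.U.grad += dU
        self.b.grad += da_all.reshape(-1, 4 * hd).sum(axis=0)
        return da_all @ self.W.value.T


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip: float | None = 5.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.clip = lr, beta1, beta2, eps, clip
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        if self.clip is not None:
            norm = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params))
            if norm > self.clip:
                scale = self.clip / (norm + 1e-12)
                for p in self.params:
                    p.grad *= scale
        if self.weight_decay:
            for p in self.params:
                p.grad += self.weight_decay * p.value
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
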