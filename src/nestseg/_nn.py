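"""Minimal NHWC convolutional-network engine on NumPy.

Implements exactly the three layer kinds the nest-segmentation autoencoder
needs — 3x3 same-padding convolution, 2x2 max-pooling, 2x2 nearest-neighbour
upsampling — with hand-written backward passes and an Adam optimizer.
Convolutions are evaluated as im2col + BLAS GEMM in float32, chunked along
the batch axis so transient buffers stay small on one CPU.

Large intermediate arrays are drawn from a persistent :class:`BufferPool`
rather than allocated per step: repeated allocation of multi-megabyte arrays
is dominated by page-fault cost, and reusing pre-touched buffers keeps the
training loop GEMM-bound.

All randomness flows through explicit ``numpy.random.Generator`` objects, so
identical seeds give bit-identical weights, shuffles and training histories.
"""

from __future__ import annotations

import numpy as np

# Sub-batch size used internally by conv forward/backward to bound the size
# of im2col buffers (8 samples at 128x128, c_in=64 -> ~300 MB).
_CHUNK = 8


class BufferPool:
    """Keyed arena of reusable ndarrays.

    ``get(tag, shape)`` returns a pre-touched buffer of exactly ``shape``;
    the flat backing store for each tag grows monotonically, so steady-state
    training performs no large allocations at all.
    """

    def __init__(self):
        self._store: dict[str, np.ndarray] = {}

    def get(self, tag: str, shape: tuple[int, ...], dtype=np.float32,
            zero: bool = False) -> np.ndarray:
        size = int(np.prod(shape))
        buf = self._store.get(tag)
        if buf is None or buf.size < size or buf.dtype != np.dtype(dtype):
            buf = np.zeros(max(size, 1), dtype)  # zeros() pre-touches pages
            self._store[tag] = buf
        view = buf[:size].reshape(shape)
        if zero:
            view.fill(0)
        return view


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.negative(x, out=out)
    np.clip(out, -88.0, 88.0, out=out)  # float32 exp overflow guard
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


class Conv2DSame:
    """3x3 convolution, zero 'same' padding, optional fused activation.

    Weight layout (3, 3, c_in, c_out) with bias (c_out,), matching the
    fan-in/fan-out conventions of Glorot-uniform initialisation.
    """

    kind = "conv"

    def __init__(self, name: str, c_in: int, c_out: int, activation: str,
                 pool: BufferPool | None = None):
        if activation not in ("relu", "sigmoid", "none"):
            raise ValueError(f"unknown activation {activation!r}")
        self.name = name
        self.c_in = c_in
        self.c_out = c_out
        self.activation = activation
        self.pool = pool if pool is not None else BufferPool()
        self.W = np.zeros((3, 3, c_in, c_out), np.float32)
        self.b = np.zeros(c_out, np.float32)
        self.frozen = False
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self._col: np.ndarray | None = None
        self.dW: np.ndarray | None = None
        self.db: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def init_glorot(self, rng: np.random.Generator) -> None:
        fan_in = 9 * self.c_in
        fan_out = 9 * self.c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, self.W.shape).astype(np.float32)
        self.b = np.zeros(self.c_out, np.float32)

    # -- im2col helpers ----------------------------------------------------
    def _fill_col(self, xp: np.ndarray, col: np.ndarray, h: int, w: int) -> None:
        """col[(m,h,w,9,c)] <- 3x3 neighbourhoods of padded input xp."""
        for i in range(3):
            for j in range(3):
                col[:, :, :, 3 * i + j, :] = xp[:, i : i + h, j : j + w, :]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        wmat = self.W.reshape(9 * self.c_in, self.c_out)
        y = self.pool.get(f"{self.name}:y", (n, h, w, self.c_out))
        # single-chunk training batches keep their im2col matrix around so
        # the backward pass does not have to rebuild it
        cache_col = train and n <= _CHUNK
        self._col = None
        for i0 in range(0, n, _CHUNK):
            xs = x[i0 : i0 + _CHUNK]
            m = xs.shape[0]
            xp = self.pool.get(f"{self.name}:xp", (m, h + 2, w + 2, self.c_in),
                               zero=True)
            xp[:, 1 : h + 1, 1 : w + 1, :] = xs
            col_tag = f"{self.name}:col" if cache_col else "shared:col"
            col = self.pool.get(col_tag, (m * h * w, 9 * self.c_in))
            self._fill_col(xp, col.reshape(m, h, w, 9, self.c_in), h, w)
            if cache_col:
                self._col = col
            ys = y[i0 : i0 + m].reshape(m * h * w, self.c_out)
            np.matmul(col, wmat, out=ys)
            ys += self.b
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
        elif self.activation == "sigmoid":
            np.negative(y, out=y)
            np.clip(y, -88.0, 88.0, out=y)  # float32 exp overflow guard
            np.exp(y, out=y)
            y += 1.0
            np.reciprocal(y, out=y)
        if train:
            self._x, self._y = x, y
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True,
                 preact_grad: bool = False) -> np.ndarray | None:
        """Backprop ``dy`` (gradient w.r.t. this layer's output, or w.r.t.
        its pre-activation when ``preact_grad``).  ``dy`` is modified in
        place when an activation gradient is applied."""
        x, y = self._x, self._y
        assert x is not None and y is not None, "forward(train=True) required"
        if not preact_grad and self.activation != "none":
            mask = self.pool.get(f"{self.name}:gmask", y.shape)
            if self.activation == "relu":
                # sign(y) is the 0/1 ReLU indicator since y = relu(...) >= 0
                np.sign(y, out=mask)
            else:  # sigmoid: y * (1 - y)
                np.subtract(1.0, y, out=mask)
                mask *= y
            dy = np.multiply(dy, mask, out=dy)
        n, h, w, _ = x.shape
        wmat = self.W.reshape(9 * self.c_in, self.c_out)
        dW = np.zeros((9 * self.c_in, self.c_out), np.float32)
        db = np.zeros(self.c_out, np.float32)
        dx = self.pool.get(f"{self.name}:dx", x.shape) if need_dx else None
        for i0 in range(0, n, _CHUNK):
            xs = x[i0 : i0 + _CHUNK]
            m = xs.shape[0]
            dys = dy[i0 : i0 + m].reshape(m * h * w, self.c_out)
            if self._col is not None:
                col = self._col
            else:
                xp = self.pool.get(f"{self.name}:xp",
                                   (m, h + 2, w + 2, self.c_in), zero=True)
                xp[:, 1 : h + 1, 1 : w + 1, :] = xs
                col = self.pool.get("shared:col", (m * h * w, 9 * self.c_in))
                self._fill_col(xp, col.reshape(m, h, w, 9, self.c_in), h, w)
            dW += col.T @ dys
            db += dys.sum(axis=0)
            if need_dx:
                dcol = self.pool.get("shared:dcol", (m * h * w, 9 * self.c_in))
                np.matmul(dys, wmat.T, out=dcol)
                dc = dcol.reshape(m, h, w, 9, self.c_in)
                dxp = self.pool.get("shared:dxp",
                                    (m, h + 2, w + 2, self.c_in), zero=True)
                for i in range(3):
                    for j in range(3):
                        dxp[:, i : i + h, j : j + w, :] += dc[:, :, :, 3 * i + j, :]
                dx[i0 : i0 + m] = dxp[:, 1 : h + 1, 1 : w + 1, :]
        self.dW = dW.reshape(self.W.shape)
        self.db = db
        self._x = self._y = self._col = None
        return dx


class MaxPool2:
    """2x2 max-pooling, stride 2, exact single-winner backward."""

    kind = "maxpool"
    n_params = 0

    def __init__(self, name: str, pool: BufferPool | None = None):
        self.name = name
        self.pool = pool if pool is not None else BufferPool()
        self.frozen = False
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        v = self.pool.get(f"{self.name}:v", (n, h2, w2, 4, c))
        v.reshape(n, h2, w2, 2, 2, c)[...] = x.reshape(
            n, h2, 2, w2, 2, c
        ).transpose(0, 1, 3, 2, 4, 5)
        y = self.pool.get(f"{self.name}:y", (n, h2, w2, c))
        np.max(v, axis=3, out=y)
        if train:
            # first-wins argmax over the 4 window cells via pairwise
            # comparisons (much faster than np.argmax on a middle axis)
            a, b2, c2, d = (v[:, :, :, k, :] for k in range(4))
            m1 = np.maximum(a, b2)
            m2 = np.maximum(c2, d)
            idx = self.pool.get(f"{self.name}:idx", (n, h2, w2, c), np.int64)
            idx[...] = np.where(m2 > m1, 2 + (d > c2), (b2 > a).astype(np.int64))
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._idx, self._shape
        h2, w2 = h // 2, w // 2
        dv = self.pool.get(f"{self.name}:dv", (n, h2, w2, 4, c), zero=True)
        np.put_along_axis(dv, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = self.pool.get(f"{self.name}:dx", (n, h, w, c))
        dx.reshape(n, h2, 2, w2, 2, c)[...] = dv.reshape(
            n, h2, w2, 2, 2, c
        ).transpose(0, 1, 3, 2, 4, 5)
        self._idx = self._shape = None
        return dx


class Upsample2:
    """2x2 nearest-neighbour upsampling (each pixel repeated into a 2x2 block)."""

    kind = "upsample"
    n_params = 0

    def __init__(self, name: str, pool: BufferPool | None = None):
        self.name = name
        self.pool = pool if pool is not None else BufferPool()
        self.frozen = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        y = self.pool.get(f"{self.name}:y", (n, 2 * h, 2 * w, c))
        y.reshape(n, h, 2, w, 2, c)[...] = x[:, :, None, :, None, :]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        dx = self.pool.get(f"{self.name}:dx", (n, h // 2, w // 2, c))
        np.sum(dy.reshape(n, h // 2, 2, w // 2, 2, c), axis=(2, 4), out=dx)
        return dx


class Adam:
    """Adam with conventional moment parameters; one slot pair per conv layer."""

    def __init__(self, layers, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.slots = {}
        for layer in layers:
            if layer.kind == "conv":
                self.slots[layer.name] = [
                    np.zeros_like(layer.W), np.zeros_like(layer.W),
                    np.zeros_like(layer.b), np.zeros_like(layer.b),
                ]

    def step(self, layers, lr: float) -> None:
        self.t += 1
        b1, b2, eps, t = self.beta1, self.beta2, self.eps, self.t
        corr = np.sqrt(1.0 - b2**t) / (1.0 - b1**t)
        for layer in layers:
            if layer.kind != "conv" or layer.frozen or layer.dW is None:
                continue
            mW, vW, mb, vb = self.slots[layer.name]
            for p, g, m, v in ((layer.W, layer.dW, mW, vW),
                               (layer.b, layer.db, mb, vb)):
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * g * g
                p -= (lr * corr) * m / (np.sqrt(v) + eps)
            layer.dW = layer.db = None
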