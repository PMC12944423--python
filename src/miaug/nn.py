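"""Minimal feed-forward neural-network core (NumPy, hand-written gradients).

Deliberately small: exactly the layers the package's models need — temporal
1-D convolutions applied per channel row, a depthwise spatial convolution
across electrodes, batch normalization, ELU, average pooling along time,
dropout, dense layers — plus Adam and softmax cross-entropy.  Every layer
implements ``forward``/``backward`` explicitly; correctness is pinned by
finite-difference gradient checks in the test suite.

Array convention for convolutional layers: ``(batch, maps, rows, time)``
(rows = electrode rows before spatial filtering, 1 after).  All parameters
are float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: holds ``params``/``grads`` as parallel lists of arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(k: int) -> tuple[int, int]:
    # 'same' padding for stride-1 convolution; even kernels pad one more on the right
    left = (k - 1) // 2
    return left, k - 1 - left


class TemporalConv(Layer):
    """1-D convolution along the time axis, mixing input maps.

    Input ``(N, Fin, H, T)`` -> output ``(N, Fout, H, T)`` with 'same'
    padding.  No bias (batch norm always follows in our models).
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (in_maps * kernel))
        self.W = rng.normal(0.0, scale, size=(out_maps, in_maps, kernel)).astype(DTYPE)
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x, train, rng):
        from numpy.lib.stride_tricks import sliding_window_view

        k = self.kernel
        pl, pr = _same_pad(k)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        n, fin, h, _ = xp.shape
        t = x.shape[3]
        # im2col: (N, Fin, H, T, K) view, then one matmul over (Fin, K)
        cols = sliding_window_view(xp, k, axis=3)
        self._cols = cols
        y = np.tensordot(cols, self.W, axes=([1, 4], [1, 2]))  # (N, H, T, Fout)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, g):
        from numpy.lib.stride_tricks import sliding_window_view

        k = self.kernel
        pl, pr = _same_pad(k)
        t = g.shape[3]
        # dW[g,f,k] = sum_{n,h,t} x_cols[n,f,h,t,k] g[n,g,h,t]
        self.grads[0][...] = np.tensordot(g, self._cols, axes=([0, 2, 3], [0, 2, 3]))
        # dxp[s] = sum_k g[s + ... - k] w[k]: one contraction over output
        # maps, then per-tap slice adds (cheap; no big windowed temporary)
        n, fout, h, _ = g.shape
        fin = self.W.shape[1]
        p = np.tensordot(g, self.W, axes=(1, 0))  # (N, H, T, Fin, K)
        p = np.ascontiguousarray(p.transpose(4, 0, 3, 1, 2))  # (K, N, Fin, H, T)
        dxp = np.zeros((n, fin, h, t + k - 1), dtype=g.dtype)
        for j in range(k):
            dxp[:, :, :, j : j + t] += p[j]
        return np.ascontiguousarray(dxp[:, :, :, pl : pl + t])


class DepthwiseSpatialConv(Layer):
    """Depthwise convolution across all electrode rows.

    For each of the ``F`` input maps, ``D`` spatial filters spanning all
    ``H`` rows produce ``F*D`` output maps with a singleton row axis:
    ``(N, F, H, T)`` -> ``(N, F*D, 1, T)``.
    """

    def __init__(self, in_maps: int, depth_multiplier: int, n_rows: int, rng: np.random.Generator):
        super().__init__()
        self.F, self.D, self.H = in_maps, depth_multiplier, n_rows
        scale = np.sqrt(2.0 / n_rows)
        self.W = rng.normal(0.0, scale, size=(in_maps, depth_multiplier, n_rows)).astype(DTYPE)
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x, train, rng):
        self._x = x
        y = np.einsum("nfht,fdh->nfdt", x, self.W, optimize=True)
        n, f, d, t = y.shape
        return y.reshape(n, f * d, 1, t)

    def backward(self, g):
        n = g.shape[0]
        t = g.shape[3]
        gr = g.reshape(n, self.F, self.D, t)
        self.grads[0][...] = np.einsum("nfht,nfdt->fdh", self._x, gr, optimize=True)
        return np.einsum("nfdt,fdh->nfht", gr, self.W, optimize=True)


class BatchNorm(Layer):
    """Batch normalization over all axes except the map axis (axis 1)."""

    def __init__(self, n_maps: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_maps, dtype=DTYPE)
        self.beta = np.zeros(n_maps, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_maps, dtype=DTYPE)
        self.running_var = np.ones(n_maps, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    @staticmethod
    def _bshape(x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train, rng):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * invstd.reshape(shp)
        if train:
            self._cache = (xhat, invstd, axes, shp)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, g):
        xhat, invstd, axes, shp = self._cache
        m = g.size // g.shape[1]
        self.grads[0][...] = np.sum(g * xhat, axis=axes)
        self.grads[1][...] = np.sum(g, axis=axes)
        gsum = self.grads[1].reshape(shp)
        gxsum = self.grads[0].reshape(shp)
        return (self.gamma.reshape(shp) * invstd.reshape(shp) / m) * (m * g - gsum - xhat * gxsum)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train, rng):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._x, self._y = x, y
        return y

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._y + self.alpha)


class AvgPoolTime(Layer):
    """Non-overlapping average pooling along the last (time) axis."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x, train, rng):
        t = x.shape[-1]
        if t % self.k:
            raise ValueError(f"time dimension {t} not divisible by pool size {self.k}")
        self._shape = x.shape
        return x.reshape(*x.shape[:-1], t // self.k, self.k).mean(axis=-1)

    def backward(self, g):
        g = np.repeat(g, self.k, axis=-1) / self.k
        return g.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train, rng):
        for l in self.layers:
            x = l.forward(x, train, rng)
        return x

    def forward_trace(self, x, train=False, rng=None) -> list[tuple[str, tuple[int, ...]]]:
        """Forward pass recording each layer's output shape (sans batch axis)."""
        trace = []
        for l in self.layers:
            x = l.forward(x, train, rng)
            trace.append((type(l).__name__, tuple(x.shape[1:])))
        return trace

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def state(self) -> list[np.ndarray]:
        extra = []
        for l in self.layers:
            if isinstance(l, BatchNorm):
                extra += [l.running_mean, l.running_var]
        return [p.copy() for p in self.all_params + extra]

    def load_state(self, state: list[np.ndarray]) -> None:
        extra = []
        for l in self.layers:
            if isinstance(l, BatchNorm):
                extra += [l.running_mean, l.running_var]
        for dst, src in zip(self.all_params + extra, state):
            dst[...] = src


# ---------------------------------------------------------------------------
# losses and optimizer


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy from logits; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dz = p
    dz[np.arange(n), y] -= 1.0
    return float(loss), (dz / n).astype(logits.dtype)


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits against a constant target."""
    z = z.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    s = 1.0 / (1.0 + np.exp(-z))
    return float(loss), ((s - target) / z.size).astype(DTYPE)


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
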