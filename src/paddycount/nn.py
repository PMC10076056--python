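"""Minimal numpy neural-network layer stack.

Self-contained forward/backward implementations of the handful of layer
types the counting network needs — 2-D convolution (stride 1, as k²
shifted matrix products so no patch matrix is materialized), batch
normalization, ReLU/sigmoid, 2×2 max pooling, bilinear ×2 upsampling
(align-corners off), adaptive average pooling, linear layers — plus
Adam.  Layers cache what their backward pass needs; gradients accumulate
into ``Param.grad``.

Tensors are channels-last ``(N, H, W, C)`` float32, which keeps the
per-pixel channel vectors contiguous for BLAS on a single CPU.  The
stack is deliberately small: only what a stride-1 encoder/decoder
density network uses.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base: layers expose params() and state() for the optimizer/checkpoints."""

    def params(self) -> list[Param]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            cur = getattr(self, k)
            if isinstance(cur, Param):
                cur.value[...] = v
            else:
                getattr(self, k)[...] = v


def _conv_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int):
    """Stride-1 cross-correlation of (N,H,W,Cin) with (k,k,Cin,Cout).

    Returns the output and the padded input (cached for the weight
    gradient).
    """
    k = w.shape[0]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
    n, hp, wp, _ = xp.shape
    ho, wo = hp - k + 1, wp - k + 1
    y = np.zeros((n, ho, wo, w.shape[3]), DTYPE)
    for di in range(k):
        for dj in range(k):
            y += xp[:, di:di + ho, dj:dj + wo, :] @ w[di, dj]
    if b is not None:
        y += b
    return y, xp


class Conv2d(Layer):
    """k×k stride-1 convolution; 'same' padding for odd k by default.

    Weights are stored (k, k, cin, cout), He-normal initialized.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, self._xp = _conv_raw(x, self.w.value, self.b.value, self.pad)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        k, xp = self.k, self._xp
        self._xp = None
        n, ho, wo, cout = gy.shape
        gym = gy.reshape(-1, cout)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + ho, dj:dj + wo, :].reshape(-1, self.cin)
                self.w.grad[di, dj] += xs.T @ gym
        self.b.grad += gym.sum(axis=0)
        # grad wrt input: correlate gy with flipped, transposed kernels
        wflip = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)
        gx, _ = _conv_raw(gy, np.ascontiguousarray(wflip), None, k - 1 - self.pad)
        return gx

    def params(self):
        return [self.w, self.b]

    def state(self):
        return {"w": self.w.value, "b": self.b.value}

    def load_state(self, state):
        self.w.value[...] = state["w"]
        self.b.value[...] = state["b"]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, DTYPE)
        self.running_var = np.ones(c, DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = ((x - mean) * invstd).astype(DTYPE)
        self._cache = (xhat, invstd, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self._cache = None
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma.value
        if not train:
            return gxhat * invstd
        mean_g = gxhat.mean(axis=(0, 1, 2))
        mean_gx = (gxhat * xhat).mean(axis=(0, 1, 2))
        return (gxhat - mean_g - xhat * mean_gx) * invstd

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"gamma": self.gamma.value, "beta": self.beta.value,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.gamma.value[...] = state["gamma"]
        self.beta.value[...] = state["beta"]
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0).astype(DTYPE)


class Softplus(Layer):
    """log(1+exp(x)): strictly positive output with nowhere-zero gradient.

    Used for the scalar size regression, where a hard ReLU output would
    start (and stay) dead at zero.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._sig = (1.0 / (1.0 + np.exp(-x))).astype(DTYPE)
        return np.logaddexp(0.0, x).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return (gy * self._sig).astype(DTYPE)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = (1.0 / (1.0 + np.exp(-x))).astype(DTYPE)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return (gy * self._y * (1.0 - self._y)).astype(DTYPE)


class MaxPool2(Layer):
    """2×2 max pool, stride 2; input sides must be even.

    Gradient on within-window ties is split evenly (ties are measure-zero
    for continuous activations).
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        v = x.reshape(n, h // 2, 2, w // 2, 2, c)
        m = v.max(axis=(2, 4))
        self._mask = (v == m[:, :, None, :, None, :])
        return m

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mask = self._mask
        cnt = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (gy[:, :, None, :, None, :] / cnt)
        n, h2, _, w2, _, c = g.shape
        return g.reshape(n, h2 * 2, w2 * 2, c)


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear ×2 interpolation matrix, align-corners off."""
    mat = _UPSAMPLE_CACHE.get(n)
    if mat is None:
        mat = np.zeros((2 * n, n), DTYPE)
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            lo = int(np.floor(src))
            frac = src - lo
            mat[i, min(max(lo, 0), n - 1)] += 1.0 - frac
            mat[i, min(max(lo + 1, 0), n - 1)] += frac
        _UPSAMPLE_CACHE[n] = mat
    return mat


class Upsample2x(Layer):
    """Bilinear ×2 upsampling (align-corners off), as two 1-D interpolations."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._hw = (h, w)
        a = _upsample_matrix(h)
        b = _upsample_matrix(w)
        y = (a @ x.reshape(n, h, w * c)).reshape(n * 2 * h, w, c)
        y = (b @ y).reshape(n, 2 * h, 2 * w, c)
        return np.ascontiguousarray(y, DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        n, h2, w2, c = gy.shape
        a = _upsample_matrix(h)
        b = _upsample_matrix(w)
        g = (b.T @ gy.reshape(n * h2, w2, c)).reshape(n, h2, w * c)
        g = (a.T @ g).reshape(n, h, w, c)
        return np.ascontiguousarray(g, DTYPE)


class AdaptiveAvgPool2d(Layer):
    """Average pool to a fixed (s, s) output from any input size."""

    def __init__(self, out: int):
        self.out = out

    @staticmethod
    def _bins(n: int, s: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * n / s)), int(np.ceil((i + 1) * n / s))) for i in range(s)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        s = self.out
        self._inshape = x.shape
        self._hb = self._bins(h, s)
        self._wb = self._bins(w, s)
        y = np.empty((n, s, s, c), DTYPE)
        for i, (h0, h1) in enumerate(self._hb):
            for j, (w0, w1) in enumerate(self._wb):
                y[:, i, j] = x[:, h0:h1, w0:w1].mean(axis=(1, 2))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._inshape, DTYPE)
        for i, (h0, h1) in enumerate(self._hb):
            for j, (w0, w1) in enumerate(self._wb):
                area = (h1 - h0) * (w1 - w0)
                gx[:, h0:h1, w0:w1] += gy[:, i, j][:, None, None, :] / area
        return gx


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T

    def params(self):
        return [self.w, self.b]

    def state(self):
        return {"w": self.w.value, "b": self.b.value}

    def load_state(self, state):
        self.w.value[...] = state["w"]
        self.b.value[...] = state["b"]


class ConvBNReLU(Layer):
    """The backbone/parser building block: 3×3 conv + batch norm + ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, 3, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x), train))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(gy)))

    def params(self):
        return self.conv.params() + self.bn.params()

    def state(self):
        return {f"conv.{k}": v for k, v in self.conv.state().items()} | {
            f"bn.{k}": v for k, v in self.bn.state().items()}

    def load_state(self, state):
        self.conv.load_state({k[5:]: v for k, v in state.items() if k.startswith("conv.")})
        self.bn.load_state({k[3:]: v for k, v in state.items() if k.startswith("bn.")})


class Adam:
    """Adam with the standard bias correction; updates params in place."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
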