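"""Minimal CPU neural-network layers with explicit backward passes.

The untrained-network reconstruction only ever optimises one network against
one image, so a full deep-learning framework is unnecessary; these layers
implement exactly the block inventory the method needs — 3x3 convolution,
batch normalisation, leaky ReLU, 2x2 max pooling, 3x3 up-convolution
(zero-stuffed stride-2 transposed convolution) and skip concatenation — as
NumPy float32 operations.  Each layer caches what its backward pass needs;
``backward(dy)`` returns ``dL/dx`` and accumulates parameter gradients.

Tensors are channel-first ``(C, H, W)`` single images (the optimisation is
always batch-of-one).  Convolutions use im2col + BLAS matmul; gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32

# Module-level compute dtype.  float32 is the production setting; tests switch
# to float64 for tight finite-difference gradient verification.
DTYPE = np.float32

__all__ = [
    "Parameter", "Conv2d", "BatchNorm2d", "LeakyReLU", "ReLU", "Softplus", "ScaledSigmoid",
    "MaxPool2x2", "ZeroUpsample2x", "Adam",
]


class Parameter:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Conv2d:
    """3x3 same-padding convolution, stride 1, with bias.

    Weights use He (Kaiming) normal initialisation, std = sqrt(2/fan_in),
    drawn from the supplied seeded generator.  Forward and backward build a
    channel-major column matrix in a persistent buffer (nine contiguous slice
    copies) and reduce to single BLAS GEMMs, which keeps the epoch loop
    tractable on a single CPU core.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        if k % 2 != 1:
            raise ValueError("odd kernel sizes only")
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = Parameter(rng.normal(0.0, std, size=(c_out, c_in, k, k)))
        self.b = Parameter(np.zeros(c_out))
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self._xp = None     # padded-input buffer, persists across epochs
        self._cols = None   # (C*k*k, H*W) column matrix, channel-major
        self._shape = None

    def parameters(self):
        return [self.W, self.b]

    def _ensure_buffers(self, C: int, H: int, W: int, dtype) -> None:
        if self._shape == (C, H, W) and self._xp.dtype == dtype:
            return
        p = self.k // 2
        self._xp = np.zeros((C, H + 2 * p, W + 2 * p), dtype=dtype)
        self._cols = np.empty((C * self.k * self.k, H * W), dtype=dtype)
        self._shape = (C, H, W)

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        k, p = self.k, self.k // 2
        self._ensure_buffers(C, H, W, x.dtype)
        self._xp[:, p:p + H, p:p + W] = x
        cols4 = self._cols.reshape(C, k * k, H, W)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            cols4[:, idx] = self._xp[:, i:i + H, j:j + W]
        Wmat = self.W.data.reshape(self.c_out, C * k * k)
        y = Wmat @ self._cols                      # (c_out, H*W), one GEMM
        y += self.b.data[:, None]
        return y.reshape(self.c_out, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, H, W = self._shape
        k, p = self.k, self.k // 2
        dy2 = dy.reshape(self.c_out, H * W)
        gW = self.W.grad.reshape(self.c_out, C * k * k)
        gW += dy2 @ self._cols.T
        self.b.grad += dy2.sum(axis=1)
        Wmat = self.W.data.reshape(self.c_out, C * k * k)
        dcols = (Wmat.T @ dy2).reshape(C, k * k, H, W)
        dxp = np.zeros_like(self._xp)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dxp[:, i:i + H, j:j + W] += dcols[:, idx]
        return dxp[:, p:p + H, p:p + W]


class BatchNorm2d:
    """Per-channel normalisation over the spatial axes of a single image.

    Always runs with the current image's statistics: with a batch of one
    there is no separate population to estimate, so training-mode statistics
    are also used for the final clean pass.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        xc = x - mu
        var = np.mean(xc * xc, axis=(1, 2), keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * ivar
        self._cache = (xhat, ivar)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        n = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.data[:, None, None]
        s1 = dxhat.sum(axis=(1, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        return (ivar / n) * (n * dxhat - s1 - xhat * s2)


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class Softplus:
    """Smooth rectifier ``log(1 + e^x)``: strictly positive output with a
    gradient everywhere, so the all-zero output state is not absorbing."""

    def __init__(self):
        self._x = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy / (1.0 + np.exp(-self._x))


class ScaledSigmoid:
    """Sigmoid scaled to [0, scale]; the 2*pi option for full-range phases."""

    def __init__(self, scale: float = 2.0 * np.pi):
        self.scale = scale
        self._y = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = 1.0 / (1.0 + np.exp(-x))
        self._y = s
        return self.scale * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self._y
        return dy * self.scale * s * (1.0 - s)


class MaxPool2x2:
    def __init__(self):
        self._cache = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial size must be even for 2x2 pooling, got {(H, W)}")
        r = x.reshape(C, H // 2, 2, W // 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, H // 2, W // 2, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (C, H, W))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (C, H, W) = self._cache
        dr = np.zeros((C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        return dr.reshape(C, H // 2, W // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, H, W)


class ZeroUpsample2x:
    """Stride-2 zero stuffing; followed by a Conv2d it forms a 3x3 up-convolution
    (transposed convolution with learned kernel)."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        y = np.zeros((C, 2 * H, 2 * W), dtype=x.dtype)
        y[:, ::2, ::2] = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(dy[:, ::2, ::2])


def fuse_parameters(params):
    """Re-house parameters in one flat buffer (values and gradients).

    Each parameter's ``data``/``grad`` becomes a reshaped view into a shared
    contiguous array, so the optimiser can update every weight with a single
    set of vectorised operations.
    """
    params = list(params)
    total = sum(p.size for p in params)
    data = np.empty(total, dtype=DTYPE)
    grad = np.zeros(total, dtype=DTYPE)
    off = 0
    for p in params:
        sl = slice(off, off + p.size)
        data[sl] = p.data.ravel()
        p.data = data[sl].reshape(p.data.shape)
        p.grad = grad[sl].reshape(p.data.shape)
        off += p.size
    return data, grad


class Adam:
    """Adam optimiser with bias correction (beta1=0.9, beta2=0.999).

    Fuses the parameters into one flat buffer on construction; ``step`` is a
    handful of whole-buffer array operations.
    """

    def __init__(self, params, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self._data, self._grad = fuse_parameters(self.params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = np.zeros_like(self._data)
        self._v = np.zeros_like(self._data)
        self._scratch = np.empty_like(self._data)

    def zero_grad(self) -> None:
        self._grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        g, m, v, t = self._grad, self._m, self._v, self._scratch
        m *= b1
        np.multiply(g, 1.0 - b1, out=t)
        m += t
        v *= b2
        np.multiply(g, g, out=t)
        t *= 1.0 - b2
        v += t
        np.divide(v, c2, out=t)
        np.sqrt(t, out=t)
        t += self.eps
        np.divide(m, t, out=t)
        t *= self.lr / c1
        self._data -= t
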