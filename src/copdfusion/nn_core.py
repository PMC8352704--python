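"""Minimal neural-network primitives with exact backward passes.

Everything is plain ``float64`` numpy. Layers operate on batched arrays
``(N, C, H, W)`` internally; thin functional wrappers accept the single-sample
``(C, H, W)`` convention used elsewhere in the package.

Convolution is implemented as cross-correlation (no kernel flip), the modern
CNN convention; the two are equivalent under learned kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConvLayerParams",
    "DenseLayerParams",
    "conv2d_valid",
    "avg_pool",
    "sigmoid",
    "dense_forward",
    "softmax",
    "softmax_xent",
    "Conv2D",
    "AvgPool",
    "SigmoidLayer",
    "Flatten",
    "Dense",
    "glorot_uniform",
    "finite_difference_grad",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ConvLayerParams:
    """Kernels ``(out_c, in_c, k, k)``, biases ``(out_c,)`` and stride."""

    kernels: np.ndarray
    biases: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if self.kernels.ndim != 4:
            raise ValueError("kernels must be 4-D (out_c, in_c, k, k)")
        if self.kernels.shape[2] != self.kernels.shape[3]:
            raise ValueError("kernels must be square")
        if self.kernels.shape[2] < 1:
            raise ValueError("kernel size must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.biases.shape != (self.kernels.shape[0],):
            raise ValueError("biases must have one entry per output channel")


@dataclass
class DenseLayerParams:
    """Weights ``(out_dim, in_dim)`` and biases ``(out_dim,)``."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (out_dim, in_dim)")
        if self.biases.shape != (self.weights.shape[0],):
            raise ValueError("bias length must equal out_dim")


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    """Seeded uniform initialization in [-r, r], r = sqrt(6 / (fan_in + fan_out))."""
    r = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-r, r, size=shape)


# ---------------------------------------------------------------------------
# batched forward cores


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """Unfold (N, C, H, W) into columns (N, C*k*k, P*Q) for valid windows."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ph, pw = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ph * pw)
    return cols, ph, pw


def _conv_forward_cols(
    x: np.ndarray, kernels: np.ndarray, biases: np.ndarray, stride: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    n, c, h, w = x.shape
    out_c, in_c, k, _ = kernels.shape
    if c != in_c:
        raise ValueError(f"input has {c} channels, kernels expect {in_c}")
    if h < k or w < k:
        raise ValueError(f"kernel {k}x{k} larger than input {h}x{w}")
    cols, ph, pw = _im2col(x, k, stride)
    out = np.matmul(kernels.reshape(out_c, -1), cols).reshape(n, out_c, ph, pw)
    return out + biases[None, :, None, None], cols, ph, pw


def _conv_forward(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray, stride: int) -> np.ndarray:
    return _conv_forward_cols(x, kernels, biases, stride)[0]


def _conv_backward(
    x_shape: tuple[int, ...],
    cols: np.ndarray,
    kernels: np.ndarray,
    stride: int,
    g: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (d_input, d_kernels, d_biases) for the valid cross-correlation,
    reusing the cached im2col columns of the forward pass."""
    out_c, in_c, k, _ = kernels.shape
    n, _, ph, pw = g.shape
    db = g.sum(axis=(0, 2, 3))
    g_mat = g.reshape(n, out_c, ph * pw)
    # dk[o, ckk] = sum_n g_mat[n] @ cols[n].T
    dk = np.tensordot(g_mat, cols, axes=([0, 2], [0, 2])).reshape(kernels.shape)
    # gradient w.r.t. the columns, then fold back (col2im scatter-add)
    dcols = np.matmul(kernels.reshape(out_c, -1).T, g_mat)
    dcols = dcols.reshape(n, in_c, k, k, ph, pw)
    dx = np.zeros(x_shape)
    s = stride
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + s * ph : s, j : j + s * pw : s] += dcols[:, :, i, j]
    return dx, dk, db


def _pool_forward(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    if (h - size) % stride != 0 or (w - size) % stride != 0:
        raise ValueError(f"pooling {size}/{stride} leaves incomplete tiles on {h}x{w}")
    win = sliding_window_view(x, (size, size), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.mean(axis=(4, 5))


def _pool_backward(x_shape: tuple[int, ...], size: int, stride: int, g: np.ndarray) -> np.ndarray:
    dx = np.zeros(x_shape)
    _, _, ph, pw = g.shape
    share = g / (size * size)
    for i in range(size):
        for j in range(size):
            dx[:, :, i : i + stride * ph : stride, j : j + stride * pw : stride] += share
    return dx


# ---------------------------------------------------------------------------
# functional API (single sample, (C, H, W))


def conv2d_valid(x: np.ndarray, params: ConvLayerParams) -> np.ndarray:
    """Valid (no padding) multi-channel cross-correlation plus bias.

    Output spatial size is ``floor((in - k) / stride) + 1`` per axis.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("input must be 3-D (channels, height, width)")
    return _conv_forward(x[None], params.kernels, params.biases, params.stride)[0]


def avg_pool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Average pooling over full tiles; channel count preserved."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("input must be 3-D (channels, height, width)")
    if size < 1 or stride < 1:
        raise ValueError("size and stride must be positive")
    return _pool_forward(x[None], size, stride)[0]


def sigmoid(x):
    """Numerically stable elementwise logistic function 1 / (1 + e^-x).

    Evaluated via exp(-|x|) so it saturates without overflow for arbitrarily
    large |x| and keeps subnormal precision in the tails.
    """
    x = np.asarray(x, dtype=np.float64)
    e = np.exp(-np.abs(x))
    out = np.where(x >= 0, 1.0, e) / (1.0 + e)
    return out if out.ndim else float(out)


def dense_forward(x: np.ndarray, params: DenseLayerParams) -> np.ndarray:
    """Affine map ``weights @ x + biases``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (params.weights.shape[1],):
        raise ValueError(
            f"input length {x.shape} does not match in_dim {params.weights.shape[1]}"
        )
    return params.weights @ x + params.biases


def softmax(logits: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, label: int) -> tuple[np.ndarray, float]:
    """Softmax probabilities and cross-entropy loss for one sample.

    Returns ``(probabilities, -log p[label])``; shift-invariant in the logits.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim != 1:
        raise ValueError("logits must be a vector")
    if not 0 <= label < logits.shape[0]:
        raise ValueError(f"label {label} out of range for {logits.shape[0]} classes")
    z = logits - logits.max()
    logsumexp = np.log(np.exp(z).sum())
    p = np.exp(z - logsumexp)
    loss = float(logsumexp - z[label])
    return p, loss


def softmax_xent_batch(logits: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Batched softmax cross-entropy: (probs, mean loss, d_logits of the mean)."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    p = np.exp(z - logsumexp[:, None])
    loss = float((logsumexp - z[np.arange(n), labels]).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return p, loss, d / n


# ---------------------------------------------------------------------------
# layer objects (cache forward state, accumulate parameter gradients)


class Conv2D:
    def __init__(self, params: ConvLayerParams):
        self.p = params
        self.d_kernels = np.zeros_like(params.kernels)
        self.d_biases = np.zeros_like(params.biases)
        self._x_shape: tuple[int, ...] | None = None
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        out, self._cols, _, _ = _conv_forward_cols(
            x, self.p.kernels, self.p.biases, self.p.stride
        )
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward called before forward")
        if g.shape[:2] != (self._x_shape[0], self.p.kernels.shape[0]):
            raise ValueError("upstream gradient shape mismatch with cached state")
        dx, self.d_kernels, self.d_biases = _conv_backward(
            self._x_shape, self._cols, self.p.kernels, self.p.stride, g
        )
        return dx

    def step(self, lr: float) -> None:
        self.p.kernels -= lr * self.d_kernels
        self.p.biases -= lr * self.d_biases


class AvgPool:
    def __init__(self, size: int, stride: int):
        self.size = size
        self.stride = stride
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return _pool_forward(x, self.size, self.stride)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._shape is None:
            raise RuntimeError("backward called before forward")
        return _pool_backward(self._shape, self.size, self.stride, g)

    def step(self, lr: float) -> None:  # no parameters
        pass


class SigmoidLayer:
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._y is None:
            raise RuntimeError("backward called before forward")
        return g * self._y * (1.0 - self._y)

    def step(self, lr: float) -> None:
        pass


class Flatten:
    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)

    def step(self, lr: float) -> None:
        pass


class InputScale:
    """Fixed affine input normalization ``gain * (x - offset)``; no parameters.

    Maps [0, 1] intensities to [-1, 1] by default so the first sigmoid stage
    does not start saturated at a constant operating point.
    """

    def __init__(self, offset: float = 0.5, gain: float = 2.0):
        self.offset = offset
        self.gain = gain

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.gain * (x - self.offset)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.gain * g

    def step(self, lr: float) -> None:
        pass


class Dense:
    def __init__(self, params: DenseLayerParams):
        self.p = params
        self.d_weights = np.zeros_like(params.weights)
        self.d_biases = np.zeros_like(params.biases)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.p.weights.shape[1]:
            raise ValueError(
                f"input dim {x.shape[1]} does not match in_dim {self.p.weights.shape[1]}"
            )
        self._x = x
        return x @ self.p.weights.T + self.p.biases

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before forward")
        self.d_weights = g.T @ self._x
        self.d_biases = g.sum(axis=0)
        return g @ self.p.weights

    def step(self, lr: float) -> None:
        self.p.weights -= lr * self.d_weights
        self.p.biases -= lr * self.d_biases


# ---------------------------------------------------------------------------
# gradient checking


def finite_difference_grad(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` w.r.t. every entry of ``x``.

    ``x`` is perturbed in place and restored; ``f`` takes no arguments.
    """
    grad = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + h
        fp = f()
        x[idx] = orig - h
        fm = f()
        x[idx] = orig
        grad[idx] = (fp - fm) / (2.0 * h)
        it.iternext()
    return grad
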