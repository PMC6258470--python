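"""Minimal 3D convolutional network layers in numpy.

Convolutions are lowered to matrix multiplications (im2col) so that both the
forward and the backward pass run as BLAS GEMMs. Layout convention is
channels-first: activations have shape ``(batch, channels, d, h, w)``.

The backward pass of a convolution computes the input gradient as a full
correlation of the (zero-padded) output gradient with the spatially flipped,
channel-transposed filters, again via im2col.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless unless it owns parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, D, H, W) -> (B * P, C * k^3) with P the number of output voxels."""
    windows = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    b, c, d, h, w = windows.shape[:5]
    cols = windows.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    return np.ascontiguousarray(cols).reshape(b * d * h * w, c * k**3), (d, h, w)


try:
    from . import _conv_kernels
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _conv_kernels = None


class Conv3d(Layer):
    """Valid (unpadded), stride-1 cross-correlation.

    Runs through the compiled direct kernels when numba is importable and
    falls back to an im2col + GEMM formulation otherwise; both compute the
    identical quantity. ``compute_input_grad`` is switched off for the first
    layer of a network during training (nothing consumes that gradient), but
    saliency computation re-enables it on the fly.
    """

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k**3
        fan_out = c_out * k**3
        self.W = glorot_uniform(rng, (c_out, c_in, k, k, k), fan_in, fan_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.compute_input_grad = True
        self._x: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        if _conv_kernels is not None:
            return _conv_kernels.conv3d_forward(
                np.ascontiguousarray(x), self.W, self.b)
        cols, (d, h, w) = _im2col(x, self.k)
        y = cols @ self.W.reshape(self.c_out, -1).T + self.b
        return y.reshape(x.shape[0], d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, grad_out):
        x = self._x
        self._x = None
        if _conv_kernels is not None:
            gy = np.ascontiguousarray(grad_out)
            gw, gb = _conv_kernels.conv3d_backward_w(
                np.ascontiguousarray(x), gy, self.k)
            self.grads[0] += gw
            self.grads[1] += gb
            if not self.compute_input_grad:
                return None
            return _conv_kernels.conv3d_backward_x(
                gy, self.W, x.shape[2], x.shape[3], x.shape[4])

        b = x.shape[0]
        gy = np.ascontiguousarray(grad_out.transpose(0, 2, 3, 4, 1))
        gy2 = gy.reshape(-1, self.c_out)
        cols, _ = _im2col(x, self.k)
        self.grads[0] += (gy2.T @ cols).astype(self.W.dtype).reshape(self.W.shape)
        self.grads[1] += gy2.sum(axis=0).astype(self.b.dtype)
        if not self.compute_input_grad:
            return None

        # full correlation with flipped filters gives the input gradient
        p = self.k - 1
        gpad = np.pad(grad_out, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        gcols, (d, h, w) = _im2col(gpad, self.k)
        W_flip = self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        W_flip = np.ascontiguousarray(W_flip).reshape(self.c_in, -1)
        gx = gcols @ W_flip.T
        return gx.reshape(b, d, h, w, self.c_in).transpose(0, 4, 1, 2, 3)


class MaxPool3d(Layer):
    """Non-overlapping max pooling with cubic window = stride."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size
        self._cache = None

    def forward(self, x, training=False, rng=None):
        s = self.size
        b, c, d, h, w = x.shape
        if d % s or h % s or w % s:
            raise ValueError(f"pooling window {s} does not tile shape {(d, h, w)}")
        xr = x.reshape(b, c, d // s, s, h // s, s, w // s, s)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d // s, h // s, w // s, s**3)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, idx)
        return out

    def backward(self, grad_out):
        (b, c, d, h, w), idx = self._cache
        s = self.size
        gx = np.zeros((b, c, d // s, h // s, w // s, s**3), dtype=grad_out.dtype)
        np.put_along_axis(gx, idx[..., None], grad_out[..., None], axis=-1)
        gx = gx.reshape(b, c, d // s, h // s, w // s, s, s, s)
        gx = gx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)
        self._cache = None
        return gx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad_out):
        gx = grad_out * self._mask
        self._mask = None
        return gx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            return x
        assert rng is not None, "training forward pass needs an rng for dropout"
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        gx = grad_out * self._mask.astype(grad_out.dtype)
        self._mask = None
        return gx


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out):
        self.grads[0] += (self._x.T @ grad_out).astype(self.W.dtype)
        self.grads[1] += grad_out.sum(axis=0).astype(self.b.dtype)
        gx = grad_out @ self.W.T
        self._x = None
        return gx


class Network:
    """A plain sequential stack with shared gradient bookkeeping."""

    def __init__(self, layers: list[Layer], dtype=np.float32) -> None:
        self.layers = layers
        self.dtype = dtype

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, grad_out: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
        first = self.layers[0]
        if isinstance(first, Conv3d):
            first.compute_input_grad = need_input_grad
        grad = np.asarray(grad_out, dtype=self.dtype)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grads(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g[...] = 0

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(sum of outputs)/d(input) with dropout inactive.

        Parameter layers cache activations as in training so the chain rule
        can run, but dropout stays off and parameter gradients are discarded.
        """
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            training = not isinstance(layer, Dropout)
            out = layer.forward(out, training=training)
        self.zero_grads()
        grad = self.backward(np.ones_like(out), need_input_grad=True)
        self.zero_grads()
        return grad
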