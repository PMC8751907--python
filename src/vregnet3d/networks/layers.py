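"""Differentiable volumetric layers on numpy arrays.

Tensors are ``(batch, channels, x, y, z)`` float64.  Convolutions are
evaluated as circular convolutions on a zero-padded domain via real FFTs,
which makes the adjoint (backward pass) an exact conjugate multiply in the
frequency domain; the zero padding of ``kernel//2`` voxels per side
guarantees the circular wrap never touches the retained "same" window, so
the result equals a linear zero-padded convolution.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = [
    "Layer", "Conv3D", "ConvTranspose3D", "BatchNorm3D", "ReLU",
    "Dropout", "MaxPool3D", "Softmax", "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: named parameters with matching gradient slots."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _kernel_spectrum(w: np.ndarray, padded_shape) -> np.ndarray:
    """rfftn of a small odd kernel embedded centered-at-origin with wrap."""
    k = w.shape[-3:]
    full = np.zeros(w.shape[:-3] + tuple(padded_shape), dtype=w.dtype)
    full[..., :k[0], :k[1], :k[2]] = w
    for ax, ksz in zip(range(-3, 0), k):
        full = np.roll(full, -(ksz // 2), axis=ax)
    return sfft.rfftn(full, axes=(-3, -2, -1))


class _SameConvCore:
    """Shared machinery: 'same' conv with pad k//2 and its exact adjoints."""

    def __init__(self, kernel: int):
        self.k = kernel
        self.p = kernel // 2

    def conv(self, x, w):
        """x (B,Ci,*N), w (Co,Ci,k,k,k) -> y (B,Co,*N); caches for adjoints."""
        p = self.p
        n = x.shape[-3:]
        s = tuple(m + 2 * p for m in n)
        xp = np.zeros(x.shape[:-3] + s, dtype=np.float64)
        xp[..., p:p + n[0], p:p + n[1], p:p + n[2]] = x
        self._xf = sfft.rfftn(xp, axes=(-3, -2, -1))
        self._wf = _kernel_spectrum(w.astype(np.float64), s)
        self._n, self._s = n, s
        yf = np.einsum("bi...,oi...->bo...", self._xf, self._wf)
        y = sfft.irfftn(yf, s=s, axes=(-3, -2, -1))
        return y[..., p:p + n[0], p:p + n[1], p:p + n[2]]

    def adjoints(self, dy):
        """Gradients w.r.t. input and kernel for the cached forward pass."""
        p = self.p
        n, s = self._n, self._s
        dyp = np.zeros(dy.shape[:-3] + s, dtype=np.float64)
        dyp[..., p:p + n[0], p:p + n[1], p:p + n[2]] = dy
        dyf = sfft.rfftn(dyp, axes=(-3, -2, -1))
        dxf = np.einsum("bo...,oi...->bi...", dyf, np.conj(self._wf))
        dxp = sfft.irfftn(dxf, s=s, axes=(-3, -2, -1))
        dx = dxp[..., p:p + n[0], p:p + n[1], p:p + n[2]]
        dwf = np.einsum("bo...,bi...->oi...", dyf, np.conj(self._xf))
        dwfull = sfft.irfftn(dwf, s=s, axes=(-3, -2, -1))
        for ax in range(-3, 0):
            dwfull = np.roll(dwfull, self.k // 2, axis=ax)
        dw = dwfull[..., :self.k, :self.k, :self.k]
        self._xf = self._wf = None
        return dx, dw


class Conv3D(Layer):
    """Odd-sized 'same' convolution, stride 1, zero padding kernel//2."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_channels, self.out_channels, self.kernel = \
            in_channels, out_channels, kernel
        fan = kernel ** 3
        self.params["w"] = glorot_uniform(
            rng, (out_channels, in_channels, kernel, kernel, kernel),
            in_channels * fan, out_channels * fan)
        self.params["b"] = np.zeros(out_channels)
        self._core = _SameConvCore(kernel)

    def forward(self, x, training=False):
        if self.kernel == 1:
            self._x1 = x
            w = self.params["w"][:, :, 0, 0, 0]
            return np.einsum("bi...,oi->bo...", x, w) \
                + self.params["b"][None, :, None, None, None]
        y = self._core.conv(x, self.params["w"])
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        if self.kernel == 1:
            w = self.params["w"][:, :, 0, 0, 0]
            dw = np.einsum("boxyz,bixyz->oi", dy, self._x1)
            self.grads["w"] = dw[:, :, None, None, None]
            self._x1 = None
            return np.einsum("bo...,oi->bi...", dy, w)
        dx, dw = self._core.adjoints(dy)
        self.grads["w"] = dw
        return dx


class ConvTranspose3D(Layer):
    """Transposed convolution, stride 2, output cropped to exactly double.

    Implemented as zero-stuffing to the doubled grid followed by a 'same'
    convolution, so each spatial dimension of the output is exactly twice
    the input regardless of kernel size.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels, self.kernel = \
            in_channels, out_channels, kernel
        fan = kernel ** 3
        self.params["w"] = glorot_uniform(
            rng, (out_channels, in_channels, kernel, kernel, kernel),
            in_channels * fan, out_channels * fan)
        self.params["b"] = np.zeros(out_channels)
        self._core = _SameConvCore(kernel)

    def forward(self, x, training=False):
        n = x.shape[-3:]
        up = np.zeros(x.shape[:-3] + tuple(2 * m for m in n), dtype=np.float64)
        up[..., ::2, ::2, ::2] = x
        y = self._core.conv(up, self.params["w"])
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4))
        dup, dw = self._core.adjoints(dy)
        self.grads["w"] = dw
        return dup[..., ::2, ::2, ::2]


class BatchNorm3D(Layer):
    """Per-channel normalization over batch and spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean \
                + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var \
                + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None, None]) / std[None, :, None, None, None]
        self._xhat, self._std = xhat, std
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        return g * xhat + b

    def backward(self, dy):
        axes = (0, 2, 3, 4)
        xhat, std = self._xhat, self._std
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        dxhat = dy * g
        mean_d = dxhat.mean(axis=axes)[None, :, None, None, None]
        mean_dx = (dxhat * xhat).mean(axis=axes)[None, :, None, None, None]
        dx = (dxhat - mean_d - xhat * mean_dx) / std[None, :, None, None, None]
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling; gradient routed to the first arg-max on ties."""

    def forward(self, x, training=False):
        b, c, nx, ny, nz = x.shape
        if nx % 2 or ny % 2 or nz % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        xr = x.reshape(b, c, nx // 2, 2, ny // 2, 2, nz // 2, 2)
        xr = np.moveaxis(xr, (3, 5, 7), (5, 6, 7)).reshape(
            b, c, nx // 2, ny // 2, nz // 2, 8)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, nx, ny, nz = self._in_shape
        flat = np.zeros((b, c, nx // 2, ny // 2, nz // 2, 8))
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(b, c, nx // 2, ny // 2, nz // 2, 2, 2, 2)
        flat = np.moveaxis(flat, (5, 6, 7), (3, 5, 7))
        return flat.reshape(b, c, nx, ny, nz)


class Softmax(Layer):
    """Channel-axis softmax."""

    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dy):
        p = self._p
        dot = (dy * p).sum(axis=1, keepdims=True)
        return p * (dy - dot)
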