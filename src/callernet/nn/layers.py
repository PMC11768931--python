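"""Layer zoo: convolutions, normalization, pooling, activations, linear.

Convolutions are computed as grouped GEMMs over sliding-window views, so the
forward pass costs exactly 2*L_out*C_out*(C_in/groups)*k MACs-equivalent FLOPs
per sample (the convention used by ``complexity``). Pooling layers are
non-overlapping (stride == kernel), which is all the architectures here use.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter, ShapeError


def kaiming_normal(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    # He init for ReLU-family activations: Var[w] = 2 / fan_in.
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


class Conv1d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size
        self.weight = Parameter(kaiming_normal(
            (out_channels, in_channels // groups, kernel_size), fan_in, _rng(rng)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def _out_len(self, L: int) -> int:
        Lo = (L + 2 * self.padding - self.kernel_size) // self.stride + 1
        if Lo <= 0:
            raise ShapeError(
                f"Conv1d({self.in_channels}->{self.out_channels}, k={self.kernel_size}): "
                f"input length {L} collapses to {Lo}")
        return Lo

    def forward(self, x):
        B, C, L = x.shape
        k, s, p, G = self.kernel_size, self.stride, self.padding, self.groups
        Lo = self._out_len(L)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        cols = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        colsg = cols.reshape(B, G, C // G, Lo, k)
        wg = self.weight.data.reshape(G, self.out_channels // G, C // G, k)
        y = np.einsum("bgclk,gock->bgol", colsg, wg, optimize=True)
        y = np.ascontiguousarray(y.reshape(B, self.out_channels, Lo), dtype=np.float32)
        if self.bias is not None:
            y += self.bias.data[:, None]
        self._xp, self._in_len = xp, L
        return y

    def backward(self, gy):
        B = gy.shape[0]
        k, s, p, G = self.kernel_size, self.stride, self.padding, self.groups
        C, L = self.in_channels, self._in_len
        Lo = gy.shape[2]
        cols = sliding_window_view(self._xp, k, axis=2)[:, :, ::s, :]
        colsg = cols.reshape(B, G, C // G, Lo, k)
        gyg = gy.reshape(B, G, self.out_channels // G, Lo)
        wg = self.weight.data.reshape(G, self.out_channels // G, C // G, k)
        dW = np.einsum("bgol,bgclk->gock", gyg, colsg, optimize=True)
        self.weight.grad += dW.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2))
        dcols = np.einsum("bgol,gock->bgclk", gyg, wg, optimize=True)
        dcols = dcols.reshape(B, C, Lo, k)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            dxp[:, :, i:i + s * Lo:s] += dcols[:, :, :, i]
        return dxp[:, :, p:p + L] if p else dxp

    def complexity(self, in_shape):
        C, L = in_shape
        Lo = self._out_len(L)
        fl = 2.0 * Lo * self.out_channels * (C // self.groups) * self.kernel_size
        if self.bias is not None:
            fl += Lo * self.out_channels
        return (self.out_channels, Lo), fl


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True, rng=None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        sh, sw = (stride, stride) if isinstance(stride, int) else stride
        ph, pw = (padding, padding) if isinstance(padding, int) else padding
        self.in_channels, self.out_channels, self.groups = in_channels, out_channels, groups
        self.kernel_size, self.stride, self.padding = (kh, kw), (sh, sw), (ph, pw)
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Parameter(kaiming_normal(
            (out_channels, in_channels // groups, kh, kw), fan_in, _rng(rng)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def _out_hw(self, H, W):
        (kh, kw), (sh, sw), (ph, pw) = self.kernel_size, self.stride, self.padding
        Ho = (H + 2 * ph - kh) // sh + 1
        Wo = (W + 2 * pw - kw) // sw + 1
        if Ho <= 0 or Wo <= 0:
            raise ShapeError(
                f"Conv2d({self.in_channels}->{self.out_channels}, k={self.kernel_size}): "
                f"input {H}x{W} collapses to {Ho}x{Wo}")
        return Ho, Wo

    def forward(self, x):
        B, C, H, W = x.shape
        (kh, kw), (sh, sw), (ph, pw) = self.kernel_size, self.stride, self.padding
        G, O = self.groups, self.out_channels
        Ho, Wo = self._out_hw(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
        cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        colsg = cols.reshape(B, G, C // G, Ho, Wo, kh, kw)
        wg = self.weight.data.reshape(G, O // G, C // G, kh, kw)
        y = np.einsum("bgchwij,gocij->bgohw", colsg, wg, optimize=True)
        y = np.ascontiguousarray(y.reshape(B, O, Ho, Wo), dtype=np.float32)
        if self.bias is not None:
            y += self.bias.data[:, None, None]
        self._xp, self._in_hw = xp, (H, W)
        return y

    def backward(self, gy):
        B, O, Ho, Wo = gy.shape
        (kh, kw), (sh, sw), (ph, pw) = self.kernel_size, self.stride, self.padding
        G, C = self.groups, self.in_channels
        H, W = self._in_hw
        cols = sliding_window_view(self._xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        colsg = cols.reshape(B, G, C // G, Ho, Wo, kh, kw)
        gyg = gy.reshape(B, G, O // G, Ho, Wo)
        wg = self.weight.data.reshape(G, O // G, C // G, kh, kw)
        dW = np.einsum("bgohw,bgchwij->gocij", gyg, colsg, optimize=True)
        self.weight.grad += dW.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        dcols = np.einsum("bgohw,gocij->bgchwij", gyg, wg, optimize=True)
        dcols = dcols.reshape(B, C, Ho, Wo, kh, kw)
        dxp = np.zeros_like(self._xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += dcols[:, :, :, :, i, j]
        if ph or pw:
            return dxp[:, :, ph:ph + H, pw:pw + W]
        return dxp

    def complexity(self, in_shape):
        C, H, W = in_shape
        Ho, Wo = self._out_hw(H, W)
        (kh, kw) = self.kernel_size
        fl = 2.0 * Ho * Wo * self.out_channels * (C // self.groups) * kh * kw
        if self.bias is not None:
            fl += Ho * Wo * self.out_channels
        return (self.out_channels, Ho, Wo), fl


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(kaiming_normal(
            (out_features, in_features), in_features, _rng(rng)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y.astype(np.float32, copy=False)

    def backward(self, gy):
        self.weight.grad += gy.T @ self._x
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.data

    def complexity(self, in_shape):
        (n,) = in_shape
        fl = 2.0 * n * self.out_features
        if self.bias is not None:
            fl += self.out_features
        return (self.out_features,), fl


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.num_features, self.momentum, self.eps = num_features, momentum, eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def _bshape(self, ndim):
        return (1, self.num_features) + (1,) * (ndim - 2)

    def forward(self, x):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // self.num_features
            unbiased = var * n / max(n - 1, 1)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(np.float32)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
            self._xhat, self._invstd, self._axes, self._n = xhat, invstd, axes, n
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shape)) * invstd.reshape(shape)
            self._xhat, self._invstd, self._axes, self._n = xhat, invstd, axes, None
        y = self.weight.data.reshape(shape) * xhat + self.bias.data.reshape(shape)
        return y.astype(np.float32, copy=False)

    def backward(self, gy):
        shape = self._bshape(gy.ndim)
        xhat, axes = self._xhat, self._axes
        self.weight.grad += (gy * xhat).sum(axis=axes)
        self.bias.grad += gy.sum(axis=axes)
        gxhat = gy * self.weight.data.reshape(shape)
        if self._n is None:  # eval mode: running stats are constants
            return gxhat * self._invstd.reshape(shape)
        n = self._n
        s1 = gxhat.sum(axis=axes, keepdims=True)
        s2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
        dx = (self._invstd.reshape(shape) / n) * (n * gxhat - s1 - xhat * s2)
        return dx.astype(np.float32, copy=False)

    def complexity(self, in_shape):
        numel = float(np.prod(in_shape))
        return in_shape, 2.0 * numel  # scale + shift


BatchNorm1d = BatchNorm
BatchNorm2d = BatchNorm


class _Activation(Module):
    def complexity(self, in_shape):
        return in_shape, float(np.prod(in_shape))


class ReLU(_Activation):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, gy):
        return gy * self._mask


class ReLU6(_Activation):
    def forward(self, x):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0).astype(np.float32, copy=False)

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(_Activation):
    def __init__(self, negative_slope=0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x).astype(np.float32, copy=False)

    def backward(self, gy):
        return np.where(self._mask, gy, self.negative_slope * gy)


class Softmax(Module):
    """Probability head over the class axis."""

    def forward(self, x):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y.astype(np.float32, copy=False)

    def backward(self, gy):
        y = self._y
        return y * (gy - (gy * y).sum(axis=1, keepdims=True))

    def complexity(self, in_shape):
        return in_shape, 3.0 * float(np.prod(in_shape))


class MaxPool1d(Module):
    def __init__(self, kernel_size):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x):
        B, C, L = x.shape
        k = self.kernel_size
        Lo = L // k
        if Lo <= 0:
            raise ShapeError(f"MaxPool1d(k={k}): input length {L} too short")
        xt = x[:, :, :Lo * k].reshape(B, C, Lo, k)
        self._idx = xt.argmax(axis=-1)
        self._in_len = L
        return np.take_along_axis(xt, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        B, C, Lo = gy.shape
        k = self.kernel_size
        dxt = np.zeros((B, C, Lo, k), dtype=gy.dtype)
        np.put_along_axis(dxt, self._idx[..., None], gy[..., None], axis=-1)
        dx = np.zeros((B, C, self._in_len), dtype=gy.dtype)
        dx[:, :, :Lo * k] = dxt.reshape(B, C, Lo * k)
        return dx

    def complexity(self, in_shape):
        C, L = in_shape
        Lo = L // self.kernel_size
        if Lo <= 0:
            raise ShapeError(f"MaxPool1d(k={self.kernel_size}): length {L} too short")
        return (C, Lo), float(C * Lo * self.kernel_size)


class AvgPool1d(Module):
    def __init__(self, kernel_size):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x):
        B, C, L = x.shape
        k = self.kernel_size
        Lo = L // k
        if Lo <= 0:
            raise ShapeError(f"AvgPool1d(k={k}): input length {L} too short")
        self._in_len = L
        return x[:, :, :Lo * k].reshape(B, C, Lo, k).mean(axis=-1)

    def backward(self, gy):
        B, C, Lo = gy.shape
        k = self.kernel_size
        dx = np.zeros((B, C, self._in_len), dtype=gy.dtype)
        dx[:, :, :Lo * k] = np.repeat(gy / k, k, axis=-1)
        return dx

    def complexity(self, in_shape):
        C, L = in_shape
        Lo = L // self.kernel_size
        if Lo <= 0:
            raise ShapeError(f"AvgPool1d(k={self.kernel_size}): length {L} too short")
        return (C, Lo), float(C * Lo * self.kernel_size)


class _Pool2dBase(Module):
    def __init__(self, kernel_size):
        super().__init__()
        self.kernel_size = (kernel_size, kernel_size) if isinstance(kernel_size, int) else tuple(kernel_size)

    def _blocks(self, x):
        B, C, H, W = x.shape
        kh, kw = self.kernel_size
        Ho, Wo = H // kh, W // kw
        if Ho <= 0 or Wo <= 0:
            raise ShapeError(f"{type(self).__name__}(k={self.kernel_size}): input {H}x{W} too small")
        xt = x[:, :, :Ho * kh, :Wo * kw].reshape(B, C, Ho, kh, Wo, kw)
        return xt.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, kh * kw), (H, W, Ho, Wo)

    def _scatter(self, dblocks, dims):
        H, W, Ho, Wo = dims
        kh, kw = self.kernel_size
        B, C = dblocks.shape[:2]
        d = dblocks.reshape(B, C, Ho, Wo, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W), dtype=dblocks.dtype)
        dx[:, :, :Ho * kh, :Wo * kw] = d.reshape(B, C, Ho * kh, Wo * kw)
        return dx

    def complexity(self, in_shape):
        C, H, W = in_shape
        kh, kw = self.kernel_size
        Ho, Wo = H // kh, W // kw
        if Ho <= 0 or Wo <= 0:
            raise ShapeError(f"{type(self).__name__}(k={self.kernel_size}): input {H}x{W} too small")
        return (C, Ho, Wo), float(C * Ho * Wo * kh * kw)


class MaxPool2d(_Pool2dBase):
    def forward(self, x):
        blocks, self._dims = self._blocks(x)
        self._idx = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        kh, kw = self.kernel_size
        dblocks = np.zeros(gy.shape + (kh * kw,), dtype=gy.dtype)
        np.put_along_axis(dblocks, self._idx[..., None], gy[..., None], axis=-1)
        return self._scatter(dblocks, self._dims)


class AvgPool2d(_Pool2dBase):
    def forward(self, x):
        blocks, self._dims = self._blocks(x)
        return blocks.mean(axis=-1)

    def backward(self, gy):
        kh, kw = self.kernel_size
        dblocks = np.broadcast_to((gy / (kh * kw))[..., None], gy.shape + (kh * kw,))
        return self._scatter(np.ascontiguousarray(dblocks), self._dims)


def _adaptive_bins(length: int, out: int) -> list[tuple[int, int]]:
    # torch-style bins; valid (non-empty) even when out > length
    return [(i * length // out, -(-((i + 1) * length) // out)) for i in range(out)]


class AdaptiveAvgPool1d(Module):
    def __init__(self, output_size: int):
        super().__init__()
        self.output_size = output_size

    def forward(self, x):
        B, C, L = x.shape
        bins = _adaptive_bins(L, self.output_size)
        y = np.empty((B, C, self.output_size), dtype=x.dtype)
        for i, (a, b) in enumerate(bins):
            y[:, :, i] = x[:, :, a:b].mean(axis=-1)
        self._bins, self._in_len = bins, L
        return y

    def backward(self, gy):
        B, C, _ = gy.shape
        dx = np.zeros((B, C, self._in_len), dtype=gy.dtype)
        for i, (a, b) in enumerate(self._bins):
            dx[:, :, a:b] += gy[:, :, i:i + 1] / (b - a)
        return dx

    def complexity(self, in_shape):
        C, L = in_shape
        return (C, self.output_size), float(C * L)


class AdaptiveAvgPool2d(Module):
    def __init__(self, output_size: tuple[int, int]):
        super().__init__()
        self.output_size = tuple(output_size)

    def forward(self, x):
        B, C, H, W = x.shape
        oh, ow = self.output_size
        hbins, wbins = _adaptive_bins(H, oh), _adaptive_bins(W, ow)
        y = np.empty((B, C, oh, ow), dtype=x.dtype)
        for i, (a, b) in enumerate(hbins):
            for j, (c, d) in enumerate(wbins):
                y[:, :, i, j] = x[:, :, a:b, c:d].mean(axis=(-2, -1))
        self._bins, self._in_hw = (hbins, wbins), (H, W)
        return y

    def backward(self, gy):
        B, C = gy.shape[:2]
        H, W = self._in_hw
        hbins, wbins = self._bins
        dx = np.zeros((B, C, H, W), dtype=gy.dtype)
        for i, (a, b) in enumerate(hbins):
            for j, (c, d) in enumerate(wbins):
                dx[:, :, a:b, c:d] += gy[:, :, i:i + 1, j:j + 1] / ((b - a) * (d - c))
        return dx

    def complexity(self, in_shape):
        C, H, W = in_shape
        return (C,) + self.output_size, float(C * H * W)


class GlobalAvgPool(Module):
    """Mean over all spatial axes -> (batch, channels)."""

    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, gy):
        shape = self._in_shape
        n = int(np.prod(shape[2:]))
        expand = gy.reshape(gy.shape + (1,) * (len(shape) - 2)) / n
        return np.broadcast_to(expand, shape).astype(gy.dtype, copy=True)

    def complexity(self, in_shape):
        return (in_shape[0],), float(np.prod(in_shape))


class Flatten(Module):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._in_shape)

    def complexity(self, in_shape):
        return (int(np.prod(in_shape)),), 0.0


class Reshape(Module):
    """Reshape per-sample data to a fixed shape (batch axis preserved)."""

    def __init__(self, *shape: int):
        super().__init__()
        self.shape = shape

    def forward(self, x):
        self._in_shape = x.shape
        if int(np.prod(x.shape[1:])) != int(np.prod(self.shape)):
            raise ShapeError(
                f"cannot reshape per-sample size {int(np.prod(x.shape[1:]))} to {self.shape}")
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape(self._in_shape)

    def complexity(self, in_shape):
        if int(np.prod(in_shape)) != int(np.prod(self.shape)):
            raise ShapeError(f"cannot reshape {in_shape} to {self.shape}")
        return self.shape, 0.0


class Dropout(Module):
    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.reseed(seed)

    def reseed(self, seed: int) -> None:
        object.__setattr__(self, "rng", np.random.default_rng(seed))

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32, copy=False)

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask

    def complexity(self, in_shape):
        return in_shape, 0.0


class Residual(Module):
    """y = body(x) + shortcut(x); identity shortcut when projection is None."""

    def __init__(self, body: Module, projection: Module | None = None):
        super().__init__()
        self.body = body
        if projection is not None:
            self.projection = projection
        else:
            object.__setattr__(self, "projection", None)

    def forward(self, x):
        y = self.body(x)
        s = self.projection(x) if self.projection is not None else x
        return y + s

    def backward(self, gy):
        gx = self.body.backward(gy)
        if self.projection is not None:
            gx = gx + self.projection.backward(gy)
        else:
            gx = gx + gy
        return gx

    def complexity(self, in_shape):
        out_shape, fl = self.body.complexity(in_shape)
        if self.projection is not None:
            p_shape, p_fl = self.projection.complexity(in_shape)
            fl += p_fl
        fl += float(np.prod(out_shape))  # the elementwise add
        return out_shape, fl


def reseed_dropout(model: Module, seed: int) -> None:
    """Give each dropout layer its own deterministic stream derived from seed."""
    streams = np.random.SeedSequence(seed).spawn(
        sum(1 for m in model.modules() if isinstance(m, Dropout)))
    i = 0
    for m in model.modules():
        if isinstance(m, Dropout):
            m.reseed(streams[i].generate_state(1)[0])
            i += 1
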