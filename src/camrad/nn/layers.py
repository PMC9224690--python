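"""Minimal CPU neural-network layers (float32, NHWC) with exact gradients.

Everything the 18-layer residual classifier needs, written on numpy: 2D
convolution (im2col-free: one GEMM per kernel offset on contiguous slice
copies, which is the fastest pure-numpy formulation on one core), batch
normalization, ReLU, 3x3/stride-2 max pooling, and a fixed bilinear
resize expressed as two small interpolation matrices (so its transpose is
the exact backward operator).  Each layer caches what its backward pass
needs; parameters expose ``.value`` and ``.grad`` for the SGD optimizer.
"""

from __future__ import annotations

import numpy as np

from ..imaging import resize_matrix

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[tuple[str, Param]]:
        return []


class Conv2d(Layer):
    """2D cross-correlation, optional stride/padding, He(fan-out) init."""

    def __init__(self, kh, kw, cin, cout, stride=1, pad=0, bias=False, rng=None,
                 init="fan_out"):
        rng = rng or np.random.default_rng()
        fan = kh * kw * (cout if init == "fan_out" else cin)
        std = np.sqrt(2.0 / fan)
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.stride, self.pad = stride, pad
        self.weight = Param(rng.standard_normal((kh, kw, cin, cout)) * std)
        self.bias = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def params(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out

    def _out_shape(self, H, W):
        Ho = (H + 2 * self.pad - self.kh) // self.stride + 1
        Wo = (W + 2 * self.pad - self.kw) // self.stride + 1
        return Ho, Wo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, H, W, _ = x.shape
        Ho, Wo = self._out_shape(H, W)
        p, s = self.pad, self.stride
        if p:
            xp = np.zeros((N, H + 2 * p, W + 2 * p, self.cin), dtype=F32)
            xp[:, p : p + H, p : p + W, :] = x
        else:
            xp = np.ascontiguousarray(x, dtype=F32)
        kk = self.kh * self.kw
        W_ = self.weight.value.reshape(kk, self.cin, self.cout)
        if self.cin * kk <= 128:
            # narrow input (e.g. the 7x7 stem on 1 channel): one wide GEMM
            # on an explicit im2col buffer beats many thin GEMMs
            col = np.empty((N * Ho * Wo, kk * self.cin), dtype=F32)
            c3 = col.reshape(N, Ho, Wo, kk, self.cin)
            for k in range(kk):
                i, j = divmod(k, self.kw)
                c3[:, :, :, k, :] = xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
            acc = col @ W_.reshape(kk * self.cin, self.cout)
            cache_x = col
        else:
            acc = None
            for k in range(kk):
                i, j = divmod(k, self.kw)
                sl = np.ascontiguousarray(
                    xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
                ).reshape(-1, self.cin)
                r = sl @ W_[k]
                acc = r if acc is None else acc + r
            cache_x = xp
        if self.bias is not None:
            acc += self.bias.value
        if train:
            self._cache = (cache_x, (N, H, W, Ho, Wo))
        return acc.reshape(N, Ho, Wo, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache_x, (N, H, W, Ho, Wo) = self._cache
        self._cache = None
        p, s = self.pad, self.stride
        kk = self.kh * self.kw
        dyf = np.ascontiguousarray(dy, dtype=F32).reshape(-1, self.cout)
        W_ = self.weight.value.reshape(kk, self.cin, self.cout)
        if self.cin * kk <= 128:
            col = cache_x
            dW = col.T @ dyf  # (kk*cin, cout)
            dcol = dyf @ W_.reshape(kk * self.cin, self.cout).T
            d3 = dcol.reshape(N, Ho, Wo, kk, self.cin)
            dxp = np.zeros((N, H + 2 * p, W + 2 * p, self.cin), dtype=F32)
            for k in range(kk):
                i, j = divmod(k, self.kw)
                dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += d3[:, :, :, k, :]
            self.weight.grad += dW.reshape(self.weight.value.shape)
        else:
            xp = cache_x
            dW = np.empty_like(W_)
            dxp = np.zeros_like(xp)
            for k in range(kk):
                i, j = divmod(k, self.kw)
                view = xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
                sl = np.ascontiguousarray(view).reshape(-1, self.cin)
                dW[k] = sl.T @ dyf
                g = dyf @ W_[k].T
                dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += g.reshape(
                    N, Ho, Wo, self.cin
                )
            self.weight.grad += dW.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=0)
        if p:
            return dxp[:, p : p + H, p : p + W, :]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xf = x.reshape(-1, x.shape[-1])
        if train:
            mean = xf.mean(axis=0)
            var = np.einsum("nc,nc->c", xf, xf) / len(xf) - mean * mean
            np.maximum(var, 0, out=var)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean.astype(F32)) * inv
        if train:
            self._cache = (xhat, inv, x.shape)
        return xhat * (self.gamma.value) + self.beta.value

    def set_stats(self, mean: np.ndarray, var: np.ndarray) -> None:
        """Overwrite running statistics (post-training recalibration)."""
        self.running_mean[:] = mean
        self.running_var[:] = var

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        n = shape[0] * shape[1] * shape[2]
        sum_dy = dy.sum(axis=(0, 1, 2))
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += sum_dy
        self.gamma.grad += sum_dy_xhat
        dx = (self.gamma.value * inv / n) * (
            n * dy - sum_dy - xhat * sum_dy_xhat
        )
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """k x k max pooling (the trunk uses 3x3, stride 2, pad 1)."""

    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=True):
        N, H, W, C = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.full((N, H + 2 * p, W + 2 * p, C), -np.inf, dtype=F32)
        xp[:, p : p + H, p : p + W, :] = x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        out = np.full((N, Ho, Wo, C), -np.inf, dtype=F32)
        arg = np.zeros((N, Ho, Wo, C), dtype=np.int8)
        for kk in range(k * k):
            i, j = divmod(kk, k)
            view = xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
            upd = view > out
            np.copyto(out, view, where=upd)
            arg[upd] = kk
        if train:
            self._cache = (arg, (N, H, W, C, Ho, Wo))
        return out

    def backward(self, dy):
        arg, (N, H, W, C, Ho, Wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dtype=F32)
        for kk in range(k * k):
            i, j = divmod(kk, k)
            sel = arg == kk
            view = dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
            view += np.where(sel, dy, 0)
        return dxp[:, p : p + H, p : p + W, :]


class BilinearResize(Layer):
    """Fixed bilinear resize (H,W) -> (Ho,Wo) as two interpolation matrices."""

    def __init__(self, in_hw, out_hw):
        self.R = resize_matrix(out_hw[0], in_hw[0]).astype(F32)
        self.C = resize_matrix(out_hw[1], in_hw[1]).astype(F32)

    def forward(self, x, train=True):
        # y[n,a,b,c] = sum_hw R[a,h] C[b,w] x[n,h,w,c], done as two batched
        # matmuls in channels-first layout
        xc = np.ascontiguousarray(x.transpose(0, 3, 1, 2))  # (N,C,H,W)
        y = self.R @ xc @ self.C.T  # (N,C,Ho,Wo)
        return np.ascontiguousarray(y.transpose(0, 2, 3, 1))

    def backward(self, dy):
        dyc = np.ascontiguousarray(dy.transpose(0, 3, 1, 2))
        dx = self.R.T @ dyc @ self.C  # (N,C,H,W)
        return np.ascontiguousarray(dx.transpose(0, 2, 3, 1))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        N, H, W, C = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (H * W), self._shape).astype(F32)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        self.weight = Param(rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin))
        self.bias = Param(np.zeros(cout))

    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy):
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value.T
        self._x = None
        return dx
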