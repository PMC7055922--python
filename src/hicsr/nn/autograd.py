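"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the contact-map networks need: broadcasted
elementwise arithmetic, matrix multiply, reductions, the sigmoid/tanh/Swish
nonlinearities, 2-D convolution (stride + zero padding) and batch
normalization.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` via a topological sweep.

All computation is float64 for reproducibility: two runs with the same seed
produce bitwise-identical results on one thread.
"""

from __future__ import annotations

import numpy as np


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helper for op results -------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._result(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._result(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._result(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._result(out_data, (self, other), backward)

    # -- reductions --------------------------------------------------------
    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g)))

        return Tensor._result(self.data.sum(), (self,), backward)

    def mean(self, axis=None):
        out_data = self.data.mean(axis=axis)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.full_like(self.data, float(g) / self.data.size))
                else:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    count = int(np.prod([self.data.shape[a] for a in axes]))
                    g_exp = np.expand_dims(g, axes)
                    self._accumulate(
                        np.broadcast_to(g_exp / count, self.data.shape).copy()
                    )

        return Tensor._result(out_data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclipped entries."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._result(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        return Tensor._result(t, (self,), backward)

    def swish(self):
        """x * sigmoid(x) (beta = 1)."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (s + self.data * s * (1.0 - s)))

        return Tensor._result(out_data, (self,), backward)


# -- convolution ------------------------------------------------------------
#
# Two evaluation strategies, chosen by patch size: im2col + BLAS matmul when
# the unrolled patch (C * kh * kw) is small, and Fourier-domain convolution
# when it is large (e.g. the 9x9 entry/exit kernels at many channels, whose
# im2col buffers would reach gigabytes).  Both produce identical results to
# floating-point accuracy; the backward pass mirrors the forward strategy.

_FFT_PATCH_THRESHOLD = 400


def _conv2d_im2col(x: "Tensor", weight: "Tensor", bias: "Tensor",
                   stride: int, padding: int, oh: int, ow: int) -> "Tensor":
    from numpy.lib.stride_tricks import sliding_window_view

    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    o, _, kh, kw = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding),
                     (padding, padding))) if padding else xd
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, c * kh * kw
    )
    wmat = wd.reshape(o, c * kh * kw)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, o, oh, ow) \
        + bias.data.reshape(1, o, 1, 1)

    def backward(g):
        g_mat = g.reshape(n, o, oh * ow).transpose(0, 2, 1)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.einsum("nlo,nlk->ok", g_mat, cols, optimize=True)
            weight._accumulate(dw.reshape(o, c, kh, kw))
        if x.requires_grad:
            dcols = (g_mat @ wmat).reshape(n, oh, ow, c, kh, kw)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
            dx_p = np.zeros((n, c, h + 2 * padding, w + 2 * padding))
            for i in range(kh):
                for j in range(kw):
                    dx_p[:, :, i:i + stride * oh:stride,
                         j:j + stride * ow:stride] += dcols[:, :, :, :, i, j]
            if padding:
                dx_p = dx_p[:, :, padding:-padding, padding:-padding]
            x._accumulate(dx_p)

    return Tensor._result(out_data, (x, weight, bias), backward)


def _freq(a: np.ndarray, fh: int, fw: int) -> np.ndarray:
    return np.fft.rfft2(a, s=(fh, fw))


def _contract(a_freq: np.ndarray, b_freq: np.ndarray, pattern: str,
              fh: int, fw: int) -> np.ndarray:
    """Per-frequency channel contraction followed by inverse FFT."""
    prod = np.einsum(pattern, a_freq, b_freq, optimize=True)
    return np.fft.irfft2(prod, s=(fh, fw))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation convention) over NCHW batches."""
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    o, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError("channel mismatch in conv2d")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("kernel larger than padded input")
    if c * kh * kw <= _FFT_PATCH_THRESHOLD:
        return _conv2d_im2col(x, weight, bias, stride, padding, oh, ow)
    fh, fw = h + kh - 1, w + kw - 1
    x_freq = _freq(xd, fh, fw)
    w_freq = _freq(wd[:, :, ::-1, ::-1], fh, fw)
    full = _contract(x_freq, w_freq, "nchw,ochw->nohw", fh, fw)
    sh, sw = kh - 1 - padding, kw - 1 - padding
    out_data = full[:, :, sh:sh + (oh - 1) * stride + 1:stride,
                    sw:sw + (ow - 1) * stride + 1:stride]
    out_data = out_data + bias.data.reshape(1, o, 1, 1)

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        # gradient dilated back onto the stride grid
        hu, wu = (oh - 1) * stride + 1, (ow - 1) * stride + 1
        g_up = np.zeros((n, o, hu, wu))
        g_up[:, :, ::stride, ::stride] = g
        if weight.requires_grad:
            # dW[o,c,k] = sum_n corr(x_pad[n,c], g_up[n,o]) at lags 0..k-1
            gh, gw = h + 2 * padding + hu - 1, w + 2 * padding + wu - 1
            x_pad = np.pad(xd, ((0, 0), (0, 0), (padding, padding),
                                (padding, padding))) if padding else xd
            xp_freq = _freq(x_pad, gh, gw)
            gf_freq = _freq(g_up[:, :, ::-1, ::-1], gh, gw)
            corr = _contract(xp_freq, gf_freq, "nchw,nohw->ochw", gh, gw)
            weight._accumulate(
                corr[:, :, hu - 1:hu - 1 + kh, wu - 1:wu - 1 + kw]
            )
        if x.requires_grad:
            # dx = full_conv(g_up, w) sampled at the padded offsets
            gh, gw = max(hu + kh - 1, h + padding), max(wu + kw - 1, w + padding)
            gu_freq = _freq(g_up, gh, gw)
            wf_freq = _freq(wd, gh, gw)
            dx_full = _contract(gu_freq, wf_freq, "nohw,ochw->nchw", gh, gw)
            x._accumulate(dx_full[:, :, padding:padding + h,
                                  padding:padding + w])

    return Tensor._result(out_data, (x, weight, bias), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and used verbatim in evaluation mode.
    """
    c = x.data.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data.reshape(1, c, 1, 1) * inv_std.reshape(1, c, 1, 1)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                g_mean = g.mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                gx_mean = (g * xhat).mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
                x._accumulate(gi * (g - g_mean - xhat * gx_mean))
                del m
            else:
                x._accumulate(gi * g)

    return Tensor._result(out_data, (x, gamma, beta), backward)
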