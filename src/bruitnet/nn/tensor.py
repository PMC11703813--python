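"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it;
:meth:`Tensor.backward` runs reverse-mode accumulation through the recorded
graph.  Only the operations the CBAM-LSTM classifier needs are implemented
(broadcast arithmetic, matmul, reductions, activations, 2-D convolution and
max-pooling, slicing, concatenation).  Everything is plain float64/float32
numpy, so forward and backward passes are bit-deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises the caller freshly allocated ``grad`` and
        # holds no other reference, so it can be stored without a copy
        if self.grad is None:
            self.grad = grad if own and grad.flags.writeable else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ub = _unbroadcast(g, self.shape)
                self._accum(ub, own=ub is not g)
            if other.requires_grad:
                ub = _unbroadcast(g, other.shape)
                other._accum(ub, own=ub is not g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g, own=True)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape), own=True)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape), own=True)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1), own=True)

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape), own=True)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        src = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(src))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full, own=True)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, np.asarray(g).item()), own=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy(), own=True)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        out = Tensor(out_data, parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full, own=True)

        out._backward = backward
        return out

    # -- activations ---------------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s), own=True)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - t**2), own=True)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask, own=True)
        return out

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * factor, own=True)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * e, own=True)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data, own=True)
        return out

    def clamp(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask, own=True)
        return out

    def batch_norm(self, gamma: "Tensor", beta: "Tensor", mean: np.ndarray,
                   var: np.ndarray, eps: float, stats_are_batch: bool = True) -> "Tensor":
        """Fused (N,C,H,W) batch normalization: gamma*(x-mean)/std + beta.

        ``mean``/``var`` are (C,) statistics: the batch moments during
        training (``stats_are_batch=True``, full batch-norm gradient) or
        frozen running estimates at inference (gradient treats them as
        constants).
        """
        x = self.data
        n_, c = x.shape[0], x.shape[1]
        dt = x.dtype
        mu = mean.reshape(1, c, 1, 1).astype(dt)
        std = np.sqrt(var.reshape(1, c, 1, 1).astype(dt) + dt.type(eps))
        xhat = (x - mu) / std
        gdat = gamma.data.reshape(1, c, 1, 1).astype(dt)
        out = Tensor(xhat * gdat + beta.data.reshape(1, c, 1, 1).astype(dt),
                     parents=(self, gamma, beta))
        m = x.shape[0] * x.shape[2] * x.shape[3]

        def backward(g):
            axes = (0, 2, 3)
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes).astype(beta.data.dtype), own=True)
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes).astype(gamma.data.dtype), own=True)
            if self.requires_grad:
                if stats_are_batch:
                    gsum = g.sum(axis=axes, keepdims=True)
                    gxhat = (g * xhat).sum(axis=axes, keepdims=True)
                    dx = (gdat / std) * (g - gsum / m - xhat * (gxhat / m))
                else:
                    dx = (gdat / std) * g
                self._accum(dx, own=True)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, out_h: int, out_w: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*kh*kw, out_h*out_w), stride 1."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + out_h, j : j + out_w]
    return cols.reshape(n, c * kh * kw, out_h * out_w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1, same-padded 2-D convolution (cross-correlation).

    x: (N, C, H, W); weight: (F, C, kh, kw); bias: (F,) or None.
    Dispatches between an im2col + BLAS matmul path (many channels) and a
    shift-add path that avoids the large column buffer (few channels, e.g.
    the CBAM spatial convolution).
    """
    n, c, h, w = x.shape
    f, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    if f == 1 and c * kh * kw > 32:
        return _conv_fft(x, weight, bias, xp, n, c, kh, kw, h, w, ph, pw)
    return _conv_im2col(x, weight, bias, xp, n, c, f, kh, kw, h, w, ph, pw)


def _conv_im2col(x, weight, bias, xp, n, c, f, kh, kw, h, w, ph, pw):
    cols = _im2col(xp, kh, kw, h, w)  # (N, C*kh*kw, H*W)
    wmat = weight.data.reshape(f, -1).astype(cols.dtype, copy=False)
    out_data = np.matmul(wmat, cols).reshape(n, f, h, w)
    if bias is not None:
        out_data = out_data + bias.data.astype(cols.dtype).reshape(1, f, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def backward(g):
        gmat = g.reshape(n, f, h * w)
        if weight.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat).reshape(n, c, kh, kw, h, w)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
            x._accum(np.ascontiguousarray(dxp[:, :, ph : ph + h, pw : pw + w]), own=True)

    out._backward = backward
    return out


def _conv_fft(x, weight, bias, xp, n, c, kh, kw, h, w, ph, pw):
    """Single-output-channel convolution via scipy's FFT convolution.

    Used for the CBAM spatial-attention convolution (F=1, C=2, 7x7), where
    an im2col buffer would dwarf the input.  Cross-correlation is FFT
    convolution with a flipped kernel; gradients are themselves
    convolutions of the padded input / output gradient.
    """
    from scipy.signal import fftconvolve

    wdat = weight.data.astype(xp.dtype, copy=False)
    flipped = wdat[:, :, ::-1, ::-1]
    out_data = fftconvolve(xp, flipped, mode="valid", axes=(2, 3)).sum(
        axis=1, keepdims=True
    )
    if bias is not None:
        out_data = out_data + bias.data.astype(xp.dtype)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data.astype(xp.dtype, copy=False), parents=parents)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)), own=True)
        if weight.requires_grad:
            # dW[0,c,i,j] = sum_{n,h,w} g[n,0,h,w] * xp[n,c,i+h,j+w];
            # einsum over a strided window view avoids any large buffer
            windows = np.lib.stride_tricks.sliding_window_view(xp, (h, w), axis=(2, 3))
            dw = np.einsum("nhw,ncijhw->cij", g[:, 0], windows)
            weight._accum(dw[np.newaxis].astype(weight.data.dtype), own=True)
        if x.requires_grad:
            # dxp[n,c] = g[n,0] (*) W[0,c]  (true convolution, full)
            dxp = fftconvolve(g, wdat, mode="full", axes=(2, 3))
            x._accum(
                np.ascontiguousarray(dxp[:, :, ph : ph + h, pw : pw + w]), own=True
            )

    out._backward = backward
    return out


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling with floor cropping of odd edges."""
    n, c, h, w = x.shape
    h2, w2 = h // size, w // size
    crop = x.data[:, :, : h2 * size, : w2 * size]
    windows = crop.reshape(n, c, h2, size, w2, size).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(n, c, h2, w2, size * size)
    idx = np.argmax(windows, axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((n, c, h2, w2, size * size), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dcrop = dwin.reshape(n, c, h2, w2, size, size).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros_like(x.data)
        dx[:, :, : h2 * size, : w2 * size] = dcrop.reshape(n, c, h2 * size, w2 * size)
        x._accum(dx, own=True)

    out._backward = backward
    return out
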