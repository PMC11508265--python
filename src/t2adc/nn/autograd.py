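"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the translation networks:
elementwise arithmetic, matmul, reductions, reflection/zero padding,
strided 2-D convolution and transposed convolution, and the usual
activations.  All data is float64; gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Tensor", "concat", "set_default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are cast to (float64 default; training
    uses float32 for speed on CPU)."""
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype.type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data

        def bwd(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(a @ b, (self, other), bwd)

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # ties share the gradient equally (deterministic)
        counts = mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            gg = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape) * mask / counts,)

        res = out_data if keepdims else out_data.squeeze(
            axis=tuple(range(self.ndim)) if axis is None else axis
        )
        return Tensor._make(res, (self,), bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def bwd(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- padding -------------------------------------------------------------
    def pad2d(self, p: int, mode: str = "constant"):
        """Pad the last two axes by ``p`` on each side (NCHW layout)."""
        if p == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(p, p), (p, p)]
        if mode == "reflect":
            out_data = np.pad(self.data, width, mode="reflect")

            def bwd(g):
                grad = np.zeros_like(self.data)
                h, w = self.shape[-2], self.shape[-1]
                # fold reflected borders back: accumulate every padded cell onto
                # its source index
                ih = _reflect_index(h, p)
                iw = _reflect_index(w, p)
                np.add.at(grad, (..., ih[:, None], iw[None, :]), g)
                return (grad,)

        else:
            out_data = np.pad(self.data, width, mode="constant")

            def bwd(g):
                sl = (Ellipsis, slice(p, p + self.shape[-2]), slice(p, p + self.shape[-1]))
                return (g[sl],)

        return Tensor._make(out_data, (self,), bwd)

    # -- convolution ---------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution (cross-correlation), NCHW × (O,C,kh,kw).

        Small kernels go through an im2col buffer; large kernels (7x7)
        use a kernel-offset accumulation that never materializes the
        kh*kw-fold expanded buffer (it would dominate memory traffic).
        """
        x = self.pad2d(padding) if padding else self
        xd = x.data
        O, C, kh, kw = weight.shape
        N, _, H, W = xd.shape
        oh = (H - kh) // stride + 1
        ow = (W - kw) // stride + 1
        if kh * kw >= 25:
            return self._conv2d_offset(x, weight, bias, stride, oh, ow)
        cols = _im2col(xd, kh, kw, stride, oh, ow)  # (N, C*kh*kw, oh*ow)
        wm = weight.data.reshape(O, C * kh * kw)
        out_data = np.matmul(wm[None], cols).reshape(N, O, oh, ow)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, O, 1, 1)

        parents = (x, weight) if bias is None else (x, weight, bias)

        def bwd(g):
            gm = g.reshape(N, O, oh * ow)
            gw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
                weight.shape
            )
            gcols = np.matmul(wm.T[None], gm)  # (N, C*kh*kw, oh*ow)
            gx = _col2im(
                gcols.reshape(N, C, kh, kw, oh, ow), H, W, stride
            )
            if bias is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        return Tensor._make(out_data, parents, bwd)

    @staticmethod
    def _conv2d_offset(x: "Tensor", weight: "Tensor", bias: "Tensor | None",
                       stride: int, oh: int, ow: int) -> "Tensor":
        xd = x.data
        O, C, kh, kw = weight.shape
        N, _, H, W = xd.shape
        wd = weight.data
        out_data = np.zeros((N, O, oh, ow), dtype=xd.dtype)
        for ki in range(kh):
            for kj in range(kw):
                xs = xd[:, :, ki:ki + oh * stride:stride,
                        kj:kj + ow * stride:stride]
                out_data += np.tensordot(wd[:, :, ki, kj], xs,
                                         axes=([1], [1])).transpose(1, 0, 2, 3)
        if bias is not None:
            out_data += bias.data.reshape(1, O, 1, 1)

        parents = (x, weight) if bias is None else (x, weight, bias)

        def bwd(g):
            gx = np.zeros_like(xd)
            gw = np.empty_like(wd)
            for ki in range(kh):
                for kj in range(kw):
                    sl = (slice(None), slice(None),
                          slice(ki, ki + oh * stride, stride),
                          slice(kj, kj + ow * stride, stride))
                    gw[:, :, ki, kj] = np.tensordot(g, xd[sl],
                                                    axes=([0, 2, 3], [0, 2, 3]))
                    gx[sl] += np.tensordot(wd[:, :, ki, kj], g,
                                           axes=([0], [1])).transpose(1, 0, 2, 3)
            if bias is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        return Tensor._make(out_data, parents, bwd)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2, padding: int = 1,
                         output_padding: int = 1):
        """Transposed 2-D convolution, weight (C_in, C_out, kh, kw)."""
        xd = self.data
        Cin, Cout, kh, kw = weight.shape
        N, _, H, W = xd.shape
        hf = (H - 1) * stride + kh  # full scatter canvas
        wf = (W - 1) * stride + kw
        ho = (H - 1) * stride - 2 * padding + kh + output_padding
        wo = (W - 1) * stride - 2 * padding + kw + output_padding
        wm = weight.data.reshape(Cin, Cout * kh * kw)
        cols = np.matmul(wm.T[None], xd.reshape(N, Cin, H * W))
        canvas = _col2im(
            cols.reshape(N, Cout, kh, kw, H, W),
            hf + output_padding, wf + output_padding, stride, canvas=True,
        )
        out_data = canvas[:, :, padding:padding + ho, padding:padding + wo]
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, Cout, 1, 1)
        out_data = np.ascontiguousarray(out_data)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def bwd(g):
            gcanvas = np.zeros((N, Cout, hf + output_padding, wf + output_padding),
                               dtype=g.dtype)
            gcanvas[:, :, padding:padding + ho, padding:padding + wo] = g
            # mirror of the scatter: gather strided slices
            gcols = np.empty((N, Cout, kh, kw, H, W), dtype=g.dtype)
            for ki in range(kh):
                for kj in range(kw):
                    gcols[:, :, ki, kj] = gcanvas[
                        :, :, ki:ki + H * stride:stride, kj:kj + W * stride:stride
                    ]
            gcols = gcols.reshape(N, Cout * kh * kw, H * W)
            gx = np.matmul(wm[None], gcols).reshape(N, Cin, H, W)
            gw = np.matmul(
                xd.reshape(N, Cin, H * W), gcols.transpose(0, 2, 1)
            ).sum(axis=0).reshape(weight.shape)
            if bias is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        return Tensor._make(out_data, parents, bwd)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() on non-scalar requires explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                pgrads = node._backward(g)
                for p, pg in zip(node._parents, pgrads):
                    if not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        out = []
        for i in range(len(datas)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            out.append(g[tuple(sl)])
        return tuple(out)

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def _reflect_index(n: int, p: int) -> np.ndarray:
    """Source index in [0, n) for each position of a length n+2p reflect-pad."""
    idx = np.arange(-p, n + p)
    idx = np.abs(idx)  # left reflection
    over = idx > n - 1
    idx[over] = 2 * (n - 1) - idx[over]
    return idx


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    N, C, H, W = x.shape
    s0, s1, s2, s3 = x.strides
    view = as_strided(
        x,
        shape=(N, C, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    # ascontiguousarray takes the fast copy path; reshape afterwards is free
    return np.ascontiguousarray(view).reshape(N, C * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, H: int, W: int, stride: int,
            canvas: bool = False) -> np.ndarray:
    """Scatter-add (N,C,kh,kw,oh,ow) patches back onto an (N,C,H,W) image."""
    N, C, kh, kw, oh, ow = cols.shape
    out = np.zeros((N, C, H, W), dtype=cols.dtype)
    for ki in range(kh):
        for kj in range(kw):
            out[:, :, ki:ki + oh * stride:stride, kj:kj + ow * stride:stride] += (
                cols[:, :, ki, kj]
            )
    return out
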