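"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the 3D fully-convolutional DenseNet needs are
implemented: same-padded 3D convolution, strided transposed convolution,
average pooling, channel concatenation, ReLU, and the segmentation losses
(in :mod:`.losses`).  Tensors are float32 with channel-first layout
``(C, X, Y, Z)``.  Convolution uses im2col + BLAS matrix multiplication;
its input gradient is the correlation of the output gradient with the
spatially flipped, channel-transposed kernel.

Gradients of every op are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Var:
    """A node in the computation tape: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents: Sequence["Var"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=DTYPE).copy()
        else:
            self.grad += g

    def backward(self, free_graph: bool = True) -> None:
        """Reverse-mode sweep from this (scalar) node.

        With ``free_graph`` (default) the tape is torn down afterwards —
        closures and parent links are cleared so activation buffers free
        immediately by reference counting instead of waiting for the
        cycle collector (a second backward pass then requires a fresh
        forward pass).
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Var] = []
        seen = set()

        def visit(v: Var) -> None:
            if id(v) in seen:
                return
            seen.add(id(v))
            for p in v.parents:
                visit(p)
            topo.append(v)

        visit(self)
        self.grad = np.ones_like(self.data)
        for v in reversed(topo):
            if v._backward is not None and v.grad is not None:
                v._backward(v.grad)
        if free_graph:
            for v in topo:
                v._backward = None
                v.parents = ()
                if not v.requires_grad:
                    v.grad = None

    def zero_grad(self) -> None:
        self.grad = None


def parameter(data, rng: Optional[np.random.Generator] = None) -> Var:
    return Var(data, requires_grad=True)


# ---------------------------------------------------------------------------
# primitive ops

def relu(x: Var) -> Var:
    mask = x.data > 0
    out = Var(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def concat(vars_: Sequence[Var]) -> Var:
    """Concatenate along the channel axis (axis 0)."""
    out = Var(np.concatenate([v.data for v in vars_], axis=0), parents=tuple(vars_))
    sizes = [v.data.shape[0] for v in vars_]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for v, lo, hi in zip(vars_, offsets[:-1], offsets[1:]):
            v._accumulate(g[lo:hi])

    out._backward = backward
    return out


def _im2col(data: np.ndarray, kernel: Tuple[int, int, int]) -> np.ndarray:
    """(C, X+2p, Y+2p, Z+2p) padded array -> (X*Y*Z, C*kx*ky*kz) patches."""
    v = sliding_window_view(data, kernel, axis=(1, 2, 3))
    c = v.shape[0]
    return np.ascontiguousarray(v.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        -1, c * kernel[0] * kernel[1] * kernel[2])


def _pad_spatial(data: np.ndarray, pad: Tuple[int, int, int]) -> np.ndarray:
    if not any(pad):
        return data
    return np.pad(data, ((0, 0), (pad[0], pad[0]), (pad[1], pad[1]), (pad[2], pad[2])))


def _corr3d_raw(data: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded correlation of (Cin, X, Y, Z) with (Cout, Cin, kx, ky, kz)."""
    cout, cin, kx, ky, kz = w.shape
    pad = (kx // 2, ky // 2, kz // 2)
    spatial = data.shape[1:]
    patches = _im2col(_pad_spatial(data, pad), (kx, ky, kz))
    out = patches @ w.reshape(cout, -1).T
    return out.T.reshape((cout,) + spatial), patches


def conv3d(x: Var, w: Var, b: Var) -> Var:
    """Same-padded stride-1 3D convolution (cross-correlation convention).

    ``w``: (C_out, C_in, kx, ky, kz) with odd kernel sizes; ``b``: (C_out,).
    """
    cout, cin, kx, ky, kz = w.data.shape
    if x.data.shape[0] != cin:
        raise ValueError(f"conv3d: input has {x.data.shape[0]} channels, kernel expects {cin}")
    out_data, patches = _corr3d_raw(x.data, w.data)
    out_data = out_data + b.data[:, None, None, None]
    out = Var(out_data, parents=(x, w, b))
    spatial = x.data.shape[1:]

    def backward(g: np.ndarray) -> None:
        g_flat = g.reshape(cout, -1).T  # (V, Cout)
        if w.requires_grad:
            dw = (g_flat.T @ patches).reshape(w.data.shape)
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.reshape(cout, -1).sum(axis=1))
        # dL/dx = correlation of g with channel-transposed, spatially flipped w
        w_t = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        dx, _ = _corr3d_raw(g, w_t)
        x._accumulate(dx)

    out._backward = backward
    return out


def avg_pool(x: Var, factors: Tuple[int, int, int]) -> Var:
    f = tuple(int(v) for v in factors)
    c, X, Y, Z = x.data.shape
    if X % f[0] or Y % f[1] or Z % f[2]:
        raise ValueError(f"avg_pool: spatial shape {(X, Y, Z)} not divisible by {f}")
    blocks = x.data.reshape(c, X // f[0], f[0], Y // f[1], f[1], Z // f[2], f[2])
    out = Var(blocks.mean(axis=(2, 4, 6)), parents=(x,))
    scale = DTYPE(1.0 / (f[0] * f[1] * f[2]))

    def backward(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(np.repeat(g, f[0], axis=1), f[1], axis=2), f[2], axis=3)
        x._accumulate(gx * scale)

    out._backward = backward
    return out


def transposed_conv3d(x: Var, w: Var, b: Var, factors: Tuple[int, int, int]) -> Var:
    """Learned upsampling: stride-``factors`` transposed convolution with
    kernel size equal to the stride (each input voxel paints one block).

    ``w``: (C_out, C_in, fx, fy, fz)."""
    f = tuple(int(v) for v in factors)
    cout, cin, fx, fy, fz = w.data.shape
    if (fx, fy, fz) != f:
        raise ValueError("transposed_conv3d: kernel size must equal the upsampling factors")
    if x.data.shape[0] != cin:
        raise ValueError("transposed_conv3d: channel mismatch")
    c, X, Y, Z = x.data.shape
    tmp = np.tensordot(w.data, x.data, axes=([1], [0]))  # (Cout,fx,fy,fz,X,Y,Z)
    out_data = tmp.transpose(0, 4, 1, 5, 2, 6, 3).reshape(cout, X * fx, Y * fy, Z * fz)
    out_data = out_data + b.data[:, None, None, None]
    out = Var(np.ascontiguousarray(out_data), parents=(x, w, b))

    def backward(g: np.ndarray) -> None:
        g6 = g.reshape(cout, X, fx, Y, fy, Z, fz).transpose(0, 2, 4, 6, 1, 3, 5)
        # g6: (Cout, fx, fy, fz, X, Y, Z)
        if w.requires_grad:
            dw = np.tensordot(g6, x.data, axes=([4, 5, 6], [1, 2, 3]))  # (Cout,fx,fy,fz,Cin)
            w._accumulate(dw.transpose(0, 4, 1, 2, 3))
        if b.requires_grad:
            b._accumulate(g.reshape(cout, -1).sum(axis=1))
        dx = np.tensordot(w.data, g6, axes=([0, 2, 3, 4], [0, 1, 2, 3]))  # (Cin,X,Y,Z)
        x._accumulate(dx)

    out._backward = backward
    return out
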