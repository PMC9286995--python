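"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the tensor operations the segmentation
network needs: 3x3 "same" convolution, 3x3 depth-wise convolution,
strided 1x1 convolution, 2x2 transposed convolution, 2x2 max pooling,
batch normalization, ReLU, channel concatenation, elementwise addition,
and fused softmax losses.  All arrays use NCHW layout.

Gradients are accumulated by a tape of closures and released by a
topological backward pass, in the style of micrograd.  Every backward
formula is covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from ._kernels import dw_correlate, dw_weight_grad

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "relu",
    "concat",
    "conv3x3",
    "depthwise3x3",
    "conv1x1",
    "conv_transpose2x2",
    "maxpool2x2",
    "batchnorm",
    "softmax",
    "softmax_cross_entropy",
    "soft_dice_loss",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _im2col3(x: np.ndarray) -> np.ndarray:
    """Shifted copies of a zero-padded NCHW array -> contiguous (N,9,C,H,W).

    Index k = 3*i + j enumerates the 3x3 kernel taps; the layout keeps
    every downstream contraction a plain BLAS matmul on contiguous data.
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, 9, c, h, w), dtype=x.dtype)
    for k in range(9):
        i, j = divmod(k, 3)
        cols[:, k] = xp[:, :, i:i + h, j:j + w]
    return cols


def _col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col3`: scatter-add (N,9,C,H,W) back to NCHW."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for k in range(9):
        i, j = divmod(k, 3)
        dxp[:, :, i:i + h, j:j + w] += dcols[:, k]
    return dxp[:, :, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# elementwise / structural ops


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        _accum(x, g * mask)

    return _make(np.where(mask, x.data, 0.0), (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# ---------------------------------------------------------------------------
# convolutions


def conv3x3(x: Tensor, w: Tensor) -> Tensor:
    """3x3 convolution, stride 1, zero 'same' padding.  w: (C_out, C_in, 3, 3)."""
    n, c, h, wd = x.data.shape
    c_out = w.data.shape[0]
    cols = _im2col3(x.data)  # (N,9,C,H,W)
    # w[o,c,i,j] -> (o, k*C + c) to match the cols (k, c) flattening
    wmat = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(c_out, 9 * c)
    out = np.matmul(wmat[None], cols.reshape(n, 9 * c, h * wd)).reshape(n, c_out, h, wd)
    del cols  # recomputed in backward: retaining every column tensor across
    # the whole graph would dominate peak memory

    def backward(g):
        cols = _im2col3(x.data)
        gmat = g.reshape(n, c_out, h * wd)
        dwmat = np.tensordot(gmat, cols.reshape(n, 9 * c, h * wd), axes=([0, 2], [0, 2]))
        _accum(w, dwmat.reshape(c_out, 3, 3, c).transpose(0, 3, 1, 2))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], gmat).reshape(n, 9, c, h, wd)
            _accum(x, _col2im3(dcols, x.data.shape))

    return _make(out, (x, w), backward)


def depthwise3x3(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel (depth-wise) 3x3 convolution.  w: (C, 3, 3).

    Runs as a fused single-pass kernel: the op is bandwidth-bound, so
    reading each pixel once (instead of nine shifted numpy passes) keeps
    it cheap relative to the dense convolutions it accompanies.
    """
    dtype = x.data.dtype
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.empty_like(x.data)
    dw_correlate(xp, np.ascontiguousarray(w.data, dtype=dtype), out)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=dtype)
        dw = np.empty(w.data.shape, dtype=dtype)
        dw_weight_grad(xp, g, dw)
        _accum(w, dw)
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1)))
            dx = np.empty_like(x.data)
            # input gradient = correlation with the 180°-flipped kernel
            dw_correlate(gp, np.ascontiguousarray(w.data[:, ::-1, ::-1], dtype=dtype), dx)
            _accum(x, dx)

    return _make(out, (x, w), backward)


def dsconv3x3(x: Tensor, w_primary: Tensor, w_depth: Tensor) -> Tensor:
    """Fused depthwise-separable block: [S1, S2] without an explicit concat.

    S1 = 3x3 convolution of ``x`` (w_primary: (half, C_in, 3, 3)); S2 =
    per-channel 3x3 convolution of S1 (w_depth: (half, 3, 3)); the output
    holds S1 in its first ``half`` channels and S2 in the rest.  Fusing
    the three steps into one graph node avoids the concatenation copy in
    both passes.
    """
    n, c, h, wd = x.data.shape
    half = w_primary.data.shape[0]
    cols = _im2col3(x.data)
    wmat = np.ascontiguousarray(w_primary.data.transpose(0, 2, 3, 1)).reshape(half, 9 * c)
    out = np.empty((n, 2 * half, h, wd), dtype=x.data.dtype)
    s1 = np.matmul(wmat[None], cols.reshape(n, 9 * c, h * wd)).reshape(n, half, h, wd)
    out[:, :half] = s1
    del cols
    dtype = out.dtype
    s1p = np.pad(s1, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s2 = np.empty_like(s1)
    dw_correlate(s1p, np.ascontiguousarray(w_depth.data, dtype=dtype), s2)
    out[:, half:] = s2
    del s2

    def backward(g):
        g1 = g[:, :half]
        g2 = np.ascontiguousarray(g[:, half:], dtype=dtype)
        dwd = np.empty(w_depth.data.shape, dtype=dtype)
        dw_weight_grad(s1p, g2, dwd)
        _accum(w_depth, dwd)
        # dL/dS1 = g1 + depthwise-transpose of g2
        g2p = np.pad(g2, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ds1 = np.empty_like(s1)
        dw_correlate(g2p, np.ascontiguousarray(w_depth.data[:, ::-1, ::-1], dtype=dtype), ds1)
        ds1 += g1
        cols = _im2col3(x.data)
        dmat = ds1.reshape(n, half, h * wd)
        dwmat = np.tensordot(dmat, cols.reshape(n, 9 * c, h * wd), axes=([0, 2], [0, 2]))
        _accum(w_primary, dwmat.reshape(half, 3, 3, c).transpose(0, 3, 1, 2))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], dmat).reshape(n, 9, c, h, wd)
            _accum(x, _col2im3(dcols, x.data.shape))

    return _make(out, (x, w_primary, w_depth), backward)


def conv1x1(x: Tensor, w: Tensor, bias: Tensor | None = None, stride: int = 1) -> Tensor:
    """1x1 convolution with optional stride (spatial subsampling).  w: (C_out, C_in)."""
    xs = x.data[:, :, ::stride, ::stride]
    out = np.einsum("nchw,oc->nohw", xs, w.data, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]
    parents = (x, w) if bias is None else (x, w, bias)

    def backward(g):
        _accum(w, np.einsum("nchw,nohw->oc", xs, g, optimize=True))
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxs = np.einsum("nohw,oc->nchw", g, w.data, optimize=True)
            dx = np.zeros_like(x.data)
            dx[:, :, ::stride, ::stride] = dxs
            _accum(x, dx)

    return _make(out, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor) -> Tensor:
    """2x2 transposed convolution with stride 2 (doubles H and W).  w: (C_in, C_out, 2, 2)."""
    n, c, h, wd = x.data.shape
    c_out = w.data.shape[1]
    out = np.empty((n, c_out, 2 * h, 2 * wd), dtype=x.data.dtype)
    tmp = np.einsum("nchw,coij->nohwij", x.data, w.data, optimize=True)
    for i in (0, 1):
        for j in (0, 1):
            out[:, :, i::2, j::2] = tmp[:, :, :, :, i, j]

    def backward(g):
        gsub = np.stack(
            [[g[:, :, i::2, j::2] for j in (0, 1)] for i in (0, 1)]
        )  # (2,2,N,O,H,W)
        _accum(w, np.einsum("nchw,ijnohw->coij", x.data, gsub, optimize=True))
        _accum(x, np.einsum("ijnohw,coij->nchw", gsub, w.data, optimize=True))

    return _make(out, (x, w), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, wd = x.data.shape
    if h % 2 or wd % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{wd}")
    xr = (
        x.data.reshape(n, c, h // 2, 2, wd // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, wd // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        dx = (
            gr.reshape(n, c, h // 2, wd // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, wd)
        )
        _accum(x, dx)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode the batch statistics normalize and the running
    statistics are updated in place; in eval mode the running statistics
    are used and treated as constants.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    x_hat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * x_hat + beta.data[None, :, None, None]

    def backward(g):
        _accum(gamma, (g * x_hat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        scale = (gamma.data * inv_std)[None, :, None, None]
        if training:
            g_mean = g.mean(axis=(0, 2, 3))[None, :, None, None]
            gx_mean = (g * x_hat).mean(axis=(0, 2, 3))[None, :, None, None]
            _accum(x, scale * (g - g_mean - x_hat * gx_mean))
        else:
            _accum(x, scale * g)

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# heads and losses


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        s = (g * p).sum(axis=axis, keepdims=True)
        _accum(x, p * (g - s))

    return _make(p, (x,), backward)


def _softmax_probs(logits: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):  # non-finite logits surface as NaN loss
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy.  logits: (N,K,H,W), labels: (N,H,W) ints."""
    p = _softmax_probs(logits.data)
    n, k, h, w = p.shape
    labels = np.asarray(labels)
    idx = (np.arange(n)[:, None, None], labels, np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    picked = p[idx[0], idx[1], idx[2], idx[3]]
    loss = float(-np.mean(np.log(np.clip(picked, 1e-12, None))))

    def backward(g):
        onehot = np.zeros_like(p)
        onehot[idx[0], idx[1], idx[2], idx[3]] = 1.0
        _accum(logits, float(g) * (p - onehot) / (n * h * w))

    return _make(np.asarray(loss), (logits,), backward)


def soft_dice_loss(logits: Tensor, labels: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft dice of the foreground channel over the whole batch."""
    p = _softmax_probs(logits.data)
    g1 = (np.asarray(labels) > 0).astype(p.dtype)
    p1 = p[:, 1]
    num = 2.0 * float((p1 * g1).sum()) + smooth
    den = float(p1.sum()) + float(g1.sum()) + smooth
    loss = 1.0 - num / den

    def backward(g):
        # d(loss)/d(p1) then through the softmax jacobian
        dp1 = -(2.0 * g1 * den - num) / (den * den)
        dp = np.zeros_like(p)
        dp[:, 1] = dp1
        s = (dp * p).sum(axis=1, keepdims=True)
        _accum(logits, float(g) * p * (dp - s))

    return _make(np.asarray(loss), (logits,), backward)
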