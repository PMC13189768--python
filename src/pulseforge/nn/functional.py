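"""Fused neural-network primitives with hand-written adjoints.

Convolution is lowered to a single BLAS matmul through ``im2col``; the
backward pass scatters patch gradients back with a small kernel-sized loop
(``col2im``), which is far cheaper than generic indexed accumulation on the
feature-map sizes this package works at.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["conv2d", "batch_norm_2d", "layer_norm", "global_avg_pool", "concat"]


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``; gradient splits back by segment."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return tensors[0]._make(data, tuple(tensors), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> patches (B*Ho*Wo, C*kh*kw) plus output spatial dims."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]           # (B, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = xshape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    dwin = dcols.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dwin[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout."""
    co, ci, kh, kw = weight.shape
    if x.shape[1] != ci:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {ci}")
    b = x.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(co, -1)
    out = cols @ wmat.T                      # (B*Ho*Wo, Co)
    if bias is not None:
        out = out + bias.data
    out_data = out.reshape(b, ho, wo, co).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, co)   # (B*Ho*Wo, Co)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            if stride == 1:
                # full correlation with spatially flipped, channel-swapped
                # weights: one BLAS call instead of a k*k scatter loop
                gcols, _, _ = _im2col(g, kh, kw, 1, kh - 1 - padding)
                wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                dx = gcols @ wflip.reshape(ci, -1).T
                h, w2 = x.shape[2], x.shape[3]
                x._accum(dx.reshape(b, h, w2, ci).transpose(0, 3, 1, 2))
            else:
                dcols = gmat @ wmat
                x._accum(_col2im(dcols, x.shape, kh, kw, stride, padding))

    return x._make(out_data, parents, backward)


def batch_norm_2d(x: Tensor, gamma: Tensor, beta: Tensor,
                  running_mean: np.ndarray, running_var: np.ndarray,
                  training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the (batch, H, W) axes of NCHW input.

    ``running_mean``/``running_var`` are updated in place in training mode and
    used verbatim in eval mode (unbiased variance in the running estimate).
    """
    axes = (0, 2, 3)
    view = (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size / x.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1.0, 1.0))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(view)) * inv_std.reshape(view)
    out_data = gamma.data.reshape(view) * xhat + beta.data.reshape(view)

    def backward(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data.reshape(view) * inv_std.reshape(view)
            if training:
                m = x.data.size / x.shape[1]
                gmean = g.mean(axis=axes).reshape(view)
                gx_xhat = (g * xhat).mean(axis=axes).reshape(view)
                x._accum(gs * (g - gmean - xhat * gx_xhat))
            else:
                x._accum(gs * g)

    return x._make(out_data, (x, gamma, beta), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis (token features)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out_data = gamma.data * xhat + beta.data
    d = x.shape[-1]

    def backward(g):
        red = tuple(range(x.ndim - 1))
        if beta.requires_grad:
            beta._accum(g.sum(axis=red))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=red))
        if x.requires_grad:
            gg = g * gamma.data
            gmean = gg.mean(axis=-1, keepdims=True)
            gx = (gg * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv_std * (gg - gmean - xhat * gx))

    return x._make(out_data, (x, gamma, beta), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC11 spatial mean."""
    return x.mean(axis=(2, 3), keepdims=True)
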