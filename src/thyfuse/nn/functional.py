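"""Spatial operations (convolution, transposed convolution, pooling, batch
norm) with hand-written backward passes.

Convolutions are lowered to matrix multiplication through im2col built on
``numpy.lib.stride_tricks.sliding_window_view``; the col2im scatter in the
backward pass loops only over the kernel footprint (k*k strided adds), so
all heavy arithmetic stays in BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, is_grad_enabled

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d", "batch_norm2d"]


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (B,C,H,W), weight: (O,C,k,k)."""
    b_sz, c_in, h, w = x.data.shape
    o_ch, _, kh, kw = weight.data.shape
    s, p = stride, padding
    xp = _pad(x.data, p)
    ho = (h + 2 * p - kh) // s + 1
    wo = (w + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (B,C,Ho,Wo,kh,kw) -> (B, Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b_sz, ho * wo, c_in * kh * kw
    )
    wmat = weight.data.reshape(o_ch, -1)
    out_mat = cols @ wmat.T
    if bias is not None:
        out_mat += bias.data
    out = Tensor(np.ascontiguousarray(out_mat.transpose(0, 2, 1)).reshape(b_sz, o_ch, ho, wo))

    needs = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    if is_grad_enabled() and needs:
        out.requires_grad = True
        out._parents = (x, weight) if bias is None else (x, weight, bias)

        def _bwd(g):
            gm = np.ascontiguousarray(g.reshape(b_sz, o_ch, ho * wo).transpose(0, 2, 1))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                dw = np.tensordot(gm, cols, axes=([0, 1], [0, 1]))
                weight._accumulate(dw.reshape(weight.data.shape))
            if x.requires_grad:
                dcols = (gm @ wmat).reshape(b_sz, ho, wo, c_in, kh, kw)
                dcols = np.ascontiguousarray(dcols.transpose(0, 3, 1, 2, 4, 5))
                dxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[..., ki, kj]
                x._accumulate(dxp[:, :, p:p + h, p:p + w] if p else dxp)

        out._backward = _bwd
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
                     padding: int = 0) -> Tensor:
    """Transposed convolution. x: (B,C,H,W), weight: (C,O,k,k)."""
    b_sz, c_in, h, w = x.data.shape
    _, o_ch, kh, kw = weight.data.shape
    s, p = stride, padding
    hf = (h - 1) * s + kh
    wf = (w - 1) * s + kw
    # contrib[b,o,i,j,ki,kj] = sum_c x[b,c,i,j] * w[c,o,ki,kj]
    contrib = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (B,H,W,O,kh,kw)
    contrib = np.ascontiguousarray(contrib.transpose(0, 3, 1, 2, 4, 5))
    yf = np.zeros((b_sz, o_ch, hf, wf), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            yf[:, :, ki:ki + s * h:s, kj:kj + s * w:s] += contrib[..., ki, kj]
    y = yf[:, :, p:hf - p, p:wf - p] if p else yf
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    out = Tensor(np.ascontiguousarray(y))

    needs = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    if is_grad_enabled() and needs:
        out.requires_grad = True
        out._parents = (x, weight) if bias is None else (x, weight, bias)

        def _bwd(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            gf = np.zeros((b_sz, o_ch, hf, wf), dtype=np.float32)
            if p:
                gf[:, :, p:hf - p, p:wf - p] = g
            else:
                gf = g
            dcontrib = np.empty((b_sz, o_ch, h, w, kh, kw), dtype=np.float32)
            for ki in range(kh):
                for kj in range(kw):
                    dcontrib[..., ki, kj] = gf[:, :, ki:ki + s * h:s, kj:kj + s * w:s]
            if weight.requires_grad:
                dw = np.tensordot(x.data, dcontrib, axes=([0, 2, 3], [0, 2, 3]))
                weight._accumulate(dw)  # (C,O,kh,kw)
            if x.requires_grad:
                dc = dcontrib.transpose(0, 2, 3, 1, 4, 5)  # (B,H,W,O,kh,kw)
                dx = np.tensordot(dc, weight.data, axes=([3, 4, 5], [1, 2, 3]))
                x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))

        out._backward = _bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 2, stride: int = 2, padding: int = 0) -> Tensor:
    b_sz, c, h, w = x.data.shape
    k, s, p = kernel, stride, padding
    if p:
        xp = np.full((b_sz, c, h + 2 * p, w + 2 * p), -np.inf, dtype=np.float32)
        xp[:, :, p:p + h, p:p + w] = x.data
    else:
        xp = x.data
    hp, wp = xp.shape[2:]
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = np.ascontiguousarray(win).reshape(b_sz, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0])

    if is_grad_enabled() and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def _bwd(g):
            ki, kj = np.divmod(idx, k)
            rows = (np.arange(ho)[None, None, :, None] * s) + ki
            colv = (np.arange(wo)[None, None, None, :] * s) + kj
            dxp = np.zeros((b_sz, c, hp, wp), dtype=np.float32)
            bi = np.arange(b_sz)[:, None, None, None]
            ci = np.arange(c)[None, :, None, None]
            np.add.at(dxp, (bi, ci, rows, colv), g)
            x._accumulate(dxp[:, :, p:p + h, p:p + w] if p else dxp)

        out._backward = _bwd
    return out


def batch_norm2d(x: Tensor, weight: Tensor, bias: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, momentum: float = 0.1, training: bool = True,
                 eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalization over (B, H, W)."""
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
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = Tensor(xhat * weight.data[None, :, None, None] + bias.data[None, :, None, None])

    if is_grad_enabled() and (x.requires_grad or weight.requires_grad or bias.requires_grad):
        out.requires_grad = True
        out._parents = (x, weight, bias)
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def _bwd(g):
            if weight.requires_grad:
                weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * weight.data[None, :, None, None]
                if training:
                    m1 = dxhat.sum(axis=(0, 2, 3)) / n
                    m2 = (dxhat * xhat).sum(axis=(0, 2, 3)) / n
                    dx = (dxhat - m1[None, :, None, None]
                          - xhat * m2[None, :, None, None]) * inv_std[None, :, None, None]
                else:
                    dx = dxhat * inv_std[None, :, None, None]
                x._accumulate(dx)

        out._backward = _bwd
    return out
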