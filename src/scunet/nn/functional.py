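"""Convolutional primitives (im2col based) with autograd support.

All tensors follow the NCHW layout.  ``conv2d`` supports a dilation
("expansion") rate, which spaces the kernel taps ``rate`` pixels apart —
rate 1 is ordinary convolution.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d", "batch_norm"]


def _out_size(n: int, k: int, stride: int, pad: int, dil: int) -> int:
    eff = dil * (k - 1) + 1
    return (n + 2 * pad - eff) // stride + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dil: int,
            oh: int, ow: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C, kh, kw, oh, ow) gather of dilated windows."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :,
                i * dil: i * dil + oh * stride: stride,
                j * dil: j * dil + ow * stride: stride,
            ]
    return cols


def _col2im(cols: np.ndarray, hp: int, wp: int, stride: int, dil: int) -> np.ndarray:
    """Scatter-add (N,C,kh,kw,oh,ow) windows back into an (N,C,Hp,Wp) array."""
    n, c, kh, kw, oh, ow = cols.shape
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :,
               i * dil: i * dil + oh * stride: stride,
               j * dil: j * dil + ow * stride: stride] += cols[:, :, i, j]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D (optionally dilated) cross-correlation.

    Parameters
    ----------
    x : (N, C_in, H, W)
    weight : (C_out, C_in, KH, KW)
    dilation : spacing between kernel taps; 1 = ordinary convolution.
    """
    if dilation < 1:
        raise ValueError(f"dilation rate must be >= 1, got {dilation}")
    if padding < 0:
        raise ValueError(f"padding must be >= 0, got {padding}")
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels but kernel expects {cin_w}")
    oh = _out_size(h, kh, stride, padding, dilation)
    ow = _out_size(w, kw, stride, padding, dilation)
    if oh <= 0 or ow <= 0:
        raise ValueError(
            f"kernel {kh}x{kw} (dilation {dilation}) larger than padded input "
            f"{h + 2 * padding}x{w + 2 * padding}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)
    cols2 = cols.reshape(n, cin * kh * kw, oh * ow)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out_data = (wmat @ cols2).reshape(n, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)
    back_pad = dilation * (kh - 1) - padding

    def bw(g):
        g = np.ascontiguousarray(g)
        gm = g.reshape(n, cout, oh * ow)
        if weight.requires_grad:
            dw = np.matmul(gm, cols2.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1 and kh == kw and back_pad >= 0:
                # input grad = dilated correlation with the flipped,
                # channel-transposed kernel (GEMM, no scatter)
                wf = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gp = np.pad(g, ((0, 0), (0, 0), (back_pad,) * 2,
                                (back_pad,) * 2))
                gcols = _im2col(gp, kh, kw, 1, dilation, h, w)
                dx = (np.ascontiguousarray(wf).reshape(cin, -1)
                      @ gcols.reshape(n, cout * kh * kw, h * w))
                x._accum(dx.reshape(n, cin, h, w))
            else:
                dcols = np.matmul(wmat.T, gm)
                dxp = _col2im(dcols.reshape(cols.shape), h + 2 * padding,
                              w + 2 * padding, stride, dilation)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accum(dxp)

    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
                     stride: int = 2, padding: int = 0,
                     output_padding: int = 0) -> Tensor:
    """Transposed 2-D convolution (learnable upsampling).

    weight : (C_in, C_out, KH, KW); output spatial size is
    ``(H-1)*stride - 2*padding + KH + output_padding``.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.data.shape
    cin_w, cout, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels but kernel expects {cin_w}")
    oh = (h - 1) * stride - 2 * padding + kh + output_padding
    ow = (w - 1) * stride - 2 * padding + kw + output_padding
    if oh <= 0 or ow <= 0:
        raise ValueError("transposed convolution produces empty output")

    wmat = weight.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(wmat.T, x.data.reshape(n, cin, h * w)).reshape(
        n, cout, kh, kw, h, w)
    # scatter into an uncropped canvas, then crop `padding` from each border;
    # output_padding leaves extra zero rows/cols at the bottom-right
    hp, wp = (h - 1) * stride + kh, (w - 1) * stride + kw
    canvas = _col2im(cols, hp, wp, stride, 1)
    out_data = np.zeros((n, cout, oh, ow), dtype=canvas.dtype)
    crop = canvas[:, :, padding: padding + oh, padding: padding + ow]
    out_data[:, :, : crop.shape[2], : crop.shape[3]] = crop
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def bw(g):
        # embed grad back into the uncropped canvas coordinates
        gc = np.zeros((n, cout, hp, wp), dtype=g.dtype)
        gh = min(oh, hp - padding)
        gw = min(ow, wp - padding)
        gc[:, :, padding: padding + gh, padding: padding + gw] = g[:, :, :gh, :gw]
        gcols = _im2col(gc, kh, kw, stride, 1, h, w).reshape(n, cout * kh * kw, h * w)
        if x.requires_grad:
            dx = np.matmul(wmat, gcols)
            x._accum(dx.reshape(n, cin, h, w))
        if weight.requires_grad:
            dw = np.matmul(x.data.reshape(n, cin, h * w),
                           gcols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by `size`."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % size or w % size:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {size}")
    hs, ws = h // size, w // size
    win = x.data.reshape(n, c, hs, size, ws, size).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, hs, ws, size * size)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, hs, ws, size, size).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, h, w))

    out._backward = bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, *,
               eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalisation over the (N, H, W) axes.

    Returns (output, batch mean, biased batch variance); the statistics are
    plain arrays for the caller's running-average bookkeeping.
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    axes = (0, 2, 3)
    cnt = n * h * w
    mu = x.data.mean(axis=axes)
    xc = x.data - mu.reshape(1, c, 1, 1)
    var = (xc * xc).mean(axis=axes)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    out = Tensor(out_data, parents=(x, gamma, beta))

    def bw(g):
        gsum = g.sum(axis=axes)
        gx = (g * xhat).sum(axis=axes)
        if beta.requires_grad:
            beta._accum(gsum)
        if gamma.requires_grad:
            gamma._accum(gx)
        if x.requires_grad:
            coef = (gamma.data * inv).reshape(1, c, 1, 1)
            dx = coef * (g - (gsum / cnt).reshape(1, c, 1, 1)
                         - xhat * (gx / cnt).reshape(1, c, 1, 1))
            x._accum(dx)

    out._backward = bw
    return out, mu, var
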