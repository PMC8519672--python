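"""Convolution and pooling kernels with hand-written backward passes.

All spatial operators work on 5-d arrays shaped ``(N, C, D, H, W)``.  The
forward/adjoint pairs are written once for ordinary convolution and reused:
a transposed convolution is exactly the adjoint of a strided convolution, so
its forward pass calls :func:`_conv_backward_input` and vice versa.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv3d", "conv_transpose3d", "maxpool3d"]


def _triple(value) -> tuple[int, int, int]:
    if np.isscalar(value):
        return (int(value),) * 3
    value = tuple(int(v) for v in value)
    if len(value) != 3:
        raise ValueError(f"expected a 3-tuple, got {value}")
    return value


def _out_size(size: int, k: int, s: int, p: int) -> int:
    return (size + 2 * p - k) // s + 1


def _windows(x_padded: np.ndarray, kernel, stride) -> np.ndarray:
    """Strided view of all kernel windows: (N, C, Do, Ho, Wo, kd, kh, kw)."""
    kd, kh, kw = kernel
    sd, sh, sw = stride
    view = sliding_window_view(x_padded, (kd, kh, kw), axis=(2, 3, 4))
    return view[:, :, ::sd, ::sh, ::sw]


def _pad(x: np.ndarray, pad, fill: float = 0.0) -> np.ndarray:
    pd, ph, pw = pad
    if pd == ph == pw == 0:
        return x
    return np.pad(
        x,
        ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
        constant_values=fill,
    )


def _conv_forward(x, w, stride, pad):
    v = _windows(_pad(x, pad), w.shape[2:], stride)
    return np.einsum("ncdhwijk,ocijk->nodhw", v, w, optimize=True)


def _conv_backward_weight(x, gy, w_shape, stride, pad):
    v = _windows(_pad(x, pad), w_shape[2:], stride)
    return np.einsum("ncdhwijk,nodhw->ocijk", v, gy, optimize=True)


def _conv_backward_input(gy, w, x_shape, stride, pad):
    """Scatter ``gy`` back through the convolution (col2im by kernel offset)."""
    n, c, d, h, wd = x_shape
    _, _, kd, kh, kw = w.shape
    sd, sh, sw = stride
    pd, ph, pw = pad
    do, ho, wo = gy.shape[2:]
    gx = np.zeros((n, c, d + 2 * pd, h + 2 * ph, wd + 2 * pw))
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                # (N,Co,P) x (Co,C) contraction for one kernel tap
                t = np.einsum("nodhw,oc->ncdhw", gy, w[:, :, i, j, k], optimize=True)
                gx[:, :, i : i + sd * do : sd, j : j + sh * ho : sh, k : k + sw * wo : sw] += t
    return gx[:, :, pd : pd + d, ph : ph + h, pw : pw + wd]


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=1, padding=0) -> Tensor:
    """Biased 3-d cross-correlation of ``x`` (N,C,D,H,W) with ``weight`` (Co,C,kd,kh,kw)."""
    stride, padding = _triple(stride), _triple(padding)
    if x.ndim != 5:
        raise ValueError(f"conv3d expects a 5-d input, got shape {x.shape}")
    if x.shape[1] != weight.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, weight expects {weight.shape[1]}"
        )
    out = _conv_forward(x.data, weight.data, stride, padding)
    if bias is not None:
        out = out + bias.data[None, :, None, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_backward_input(g, weight.data, x.shape, stride, padding))
        if weight.requires_grad:
            weight._accumulate(_conv_backward_weight(x.data, g, weight.shape, stride, padding))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out, parents, backward)


def conv_transpose3d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None,
    stride=1,
    padding=0,
    output_padding=0,
) -> Tensor:
    """Transposed 3-d convolution; ``weight`` is (Cin, Cout, kd, kh, kw)."""
    stride, padding = _triple(stride), _triple(padding)
    opad = _triple(output_padding)
    if x.ndim != 5:
        raise ValueError(f"conv_transpose3d expects a 5-d input, got shape {x.shape}")
    if x.shape[1] != weight.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, weight expects {weight.shape[0]}"
        )
    n = x.shape[0]
    cout = weight.shape[1]
    out_spatial = tuple(
        (s_in - 1) * s - 2 * p + k + op
        for s_in, s, p, k, op in zip(x.shape[2:], stride, padding, weight.shape[2:], opad)
    )
    out_shape = (n, cout, *out_spatial)
    # forward = adjoint of a conv whose input shape is out_shape
    out = _conv_backward_input(x.data, weight.data, out_shape, stride, padding)
    if bias is not None:
        out = out + bias.data[None, :, None, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if x.requires_grad:
            gx = _conv_forward(g, weight.data, stride, padding)
            # output_padding can make the strided conv of g one window larger
            gx = gx[:, :, : x.shape[2], : x.shape[3], : x.shape[4]]
            x._accumulate(gx)
        if weight.requires_grad:
            v = _windows(_pad(g, padding), weight.shape[2:], stride)
            v = v[:, :, : x.shape[2], : x.shape[3], : x.shape[4]]
            weight._accumulate(np.einsum("ncdhwijk,nodhw->ocijk", v, x.data, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out, parents, backward)


def maxpool3d(x: Tensor, kernel, stride=1, padding=0) -> Tensor:
    """Max pooling; padding uses -inf so padded cells never win."""
    kernel, stride, padding = _triple(kernel), _triple(stride), _triple(padding)
    xp = _pad(x.data, padding, fill=-np.inf)
    v = _windows(xp, kernel, stride)
    n, c, do, ho, wo = v.shape[:5]
    flat = v.reshape(n, c, do, ho, wo, -1)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        kd, kh, kw = kernel
        sd, sh, sw = stride
        off_d, rem = np.divmod(arg, kh * kw)
        off_h, off_w = np.divmod(rem, kw)
        idx = np.indices((n, c, do, ho, wo))
        pos_d = idx[2] * sd + off_d
        pos_h = idx[3] * sh + off_h
        pos_w = idx[4] * sw + off_w
        gxp = np.zeros(xp.shape)
        np.add.at(gxp, (idx[0], idx[1], pos_d, pos_h, pos_w), g)
        pd, ph, pw = padding
        x._accumulate(
            gxp[
                :,
                :,
                pd : pd + x.shape[2],
                ph : ph + x.shape[3],
                pw : pw + x.shape[4],
            ]
        )

    return Tensor._make(out, (x,), backward)
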