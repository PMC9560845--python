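"""Array-level kernels for the layer engine.

All public functions take and return plain ``numpy`` arrays laid out NCHW
and are dtype-preserving. 2-D convolution is computed tap-by-tap ("shift
and matmul"): internally the map is moved to channels-last once, and for
every kernel offset the strided window is contracted against the matching
weight slab with a single BLAS matmul. This avoids materialising a full
im2col buffer, which matters at the 800x800 resolutions the full network
runs at, and keeps every GEMM contiguous.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv2d_input_grad",
    "conv2d_weight_grad",
    "conv_transpose2d_shape",
    "maxpool2d",
    "maxpool2d_grad",
]


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _check_groups(cin: int, w_shape: tuple[int, ...], groups: int) -> None:
    cout, cin_g = w_shape[:2]
    if cin != cin_g * groups or cout % groups:
        raise ValueError(
            f"channel/group mismatch: input has {cin} channels, weight expects "
            f"{cin_g}x{groups} in / {cout} out"
        )


def conv2d(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    stride: int = 1,
    pad: int = 0,
    groups: int = 1,
) -> np.ndarray:
    """Cross-correlation of ``x`` (B,Cin,H,W) with ``w`` (Cout,Cin/g,kh,kw)."""
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    _check_groups(Cin, w.shape, groups)
    s = stride
    oh = (H + 2 * pad - kh) // s + 1
    ow = (W + 2 * pad - kw) // s + 1
    xt = _pad_hw(x, pad).transpose(0, 2, 3, 1)  # channels-last view
    Cout_g = Cout // groups
    acc = np.zeros((B * oh * ow, Cout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xt[:, i : i + s * oh : s, j : j + s * ow : s, :]
            ).reshape(B * oh * ow, Cin)
            if groups == 1:
                acc += xs @ w[:, :, i, j].T
            else:
                for g in range(groups):
                    ci = slice(g * Cin_g, (g + 1) * Cin_g)
                    co = slice(g * Cout_g, (g + 1) * Cout_g)
                    acc[:, co] += xs[:, ci] @ w[co, :, i, j].T
    y = np.ascontiguousarray(acc.reshape(B, oh, ow, Cout).transpose(0, 3, 1, 2))
    if b is not None:
        y += b.reshape(1, Cout, 1, 1)
    return y


def conv2d_input_grad(
    gy: np.ndarray,
    w: np.ndarray,
    x_shape: tuple[int, ...],
    stride: int = 1,
    pad: int = 0,
    groups: int = 1,
) -> np.ndarray:
    """Gradient of :func:`conv2d` w.r.t. its input.

    Also serves as the forward map of the stride-``s`` transposed
    convolution (with ``x_shape`` the transposed-conv *output* shape).
    """
    B, Cin, H, W = x_shape
    Cout, Cin_g, kh, kw = w.shape
    _check_groups(Cin, w.shape, groups)
    s = stride
    _, _, oh, ow = gy.shape
    Cout_g = Cout // groups
    gyt = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(B * oh * ow, Cout)
    gxt = np.zeros((B, H + 2 * pad, W + 2 * pad, Cin), dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            if groups == 1:
                t = gyt @ w[:, :, i, j]
            else:
                t = np.empty((B * oh * ow, Cin), dtype=gy.dtype)
                for g in range(groups):
                    ci = slice(g * Cin_g, (g + 1) * Cin_g)
                    co = slice(g * Cout_g, (g + 1) * Cout_g)
                    t[:, ci] = gyt[:, co] @ w[co, :, i, j]
            gxt[:, i : i + s * oh : s, j : j + s * ow : s, :] += t.reshape(B, oh, ow, Cin)
    if pad:
        gxt = gxt[:, pad:-pad, pad:-pad, :]
    return np.ascontiguousarray(gxt.transpose(0, 3, 1, 2))


def conv2d_weight_grad(
    gy: np.ndarray,
    x: np.ndarray,
    w_shape: tuple[int, ...],
    stride: int = 1,
    pad: int = 0,
    groups: int = 1,
) -> np.ndarray:
    """Gradient of :func:`conv2d` w.r.t. its weight."""
    B, Cin, _, _ = x.shape
    Cout, Cin_g, kh, kw = w_shape
    s = stride
    _, _, oh, ow = gy.shape
    Cout_g = Cout // groups
    xt = _pad_hw(x, pad).transpose(0, 2, 3, 1)
    gyt = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(B * oh * ow, Cout)
    gw = np.empty(w_shape, dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xt[:, i : i + s * oh : s, j : j + s * ow : s, :]
            ).reshape(B * oh * ow, Cin)
            if groups == 1:
                gw[:, :, i, j] = gyt.T @ xs
            else:
                for g in range(groups):
                    ci = slice(g * Cin_g, (g + 1) * Cin_g)
                    co = slice(g * Cout_g, (g + 1) * Cout_g)
                    gw[co, :, i, j] = gyt[:, co].T @ xs[:, ci]
    return gw


def conv_transpose2d_shape(h: int, w: int, k: int, stride: int, pad: int) -> tuple[int, int]:
    """Output spatial size of a transposed convolution."""
    return (h - 1) * stride - 2 * pad + k, (w - 1) * stride - 2 * pad + k


def maxpool2d(
    x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Max pooling; returns (output, flat argmax per window) for backward."""
    neg = np.finfo(x.dtype).min
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=neg)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    B, C, oh, ow = win.shape[:4]
    wf = win.reshape(B, C, oh, ow, k * k)
    idx = wf.argmax(axis=-1)
    y = np.take_along_axis(wf, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(y), idx


def maxpool2d_grad(
    gy: np.ndarray,
    idx: np.ndarray,
    x_shape: tuple[int, ...],
    k: int = 3,
    stride: int = 2,
    pad: int = 1,
) -> np.ndarray:
    B, C, H, W = x_shape
    _, _, oh, ow = gy.shape
    gxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=gy.dtype)
    hh = (np.arange(oh) * stride)[None, None, :, None] + idx // k
    ww = (np.arange(ow) * stride)[None, None, None, :] + idx % k
    bb = np.arange(B)[:, None, None, None]
    cc = np.arange(C)[None, :, None, None]
    np.add.at(gxp, (bb, cc, hh, ww), gy)
    if pad:
        return gxp[:, :, pad:-pad, pad:-pad]
    return gxp
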