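"""Strided 2-D convolution and transposed convolution primitives.

Implemented im2col-style: patches are gathered with a sliding-window view and
each direction reduces to a single large matrix multiply; the only looped
part is the 25-offset scatter-add (col2im), which is cheap relative to the
GEMMs. Padding follows the (left, right, top, bottom) convention so
asymmetric pads (e.g. (1, 2, 1, 2) for exact halving/doubling with 5x5
kernels at stride 2) are expressible.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d", "conv_output_size", "conv_transpose_output_size"]


def conv_output_size(size: int, kernel: int, stride: int, pad_lo: int, pad_hi: int) -> int:
    return (size + pad_lo + pad_hi - kernel) // stride + 1


def conv_transpose_output_size(size: int, kernel: int, stride: int, pad_lo: int, pad_hi: int) -> int:
    return (size - 1) * stride + kernel - pad_lo - pad_hi


def _gather_cols(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> (B, Ho, Wo, C, kh, kw) patch array."""
    swv = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.ascontiguousarray(swv.transpose(0, 2, 3, 1, 4, 5))


def _scatter_cols(cols: np.ndarray, out_shape: tuple, stride: int) -> np.ndarray:
    """col2im: (B, H, W, C, kh, kw) -> (B, C, Hp, Wp) with overlapping adds."""
    B, H, W, C, kh, kw = cols.shape
    out = np.zeros(out_shape, dtype=cols.dtype)
    for ki in range(kh):
        for kj in range(kw):
            out[:, :, ki:ki + (H - 1) * stride + 1:stride,
                kj:kj + (W - 1) * stride + 1:stride] += \
                cols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2,
           padding: tuple = (1, 2, 1, 2)) -> Tensor:
    """x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,)."""
    pl, pr, pt, pb = padding
    B, Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = w.data.shape
    if Cin_w != Cin:
        raise ValueError(f"conv2d channel mismatch: input has {Cin}, weight expects {Cin_w}")
    Ho = conv_output_size(H, kh, stride, pt, pb)
    Wo = conv_output_size(W, kw, stride, pl, pr)
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d output collapses for input {H}x{W} with kernel {kh}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    cols = _gather_cols(xp, kh, kw, stride).reshape(B * Ho * Wo, Cin * kh * kw)
    w2 = w.data.reshape(Cout, -1).T  # (Cin*kh*kw, Cout)
    out = cols @ w2
    out_data = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2) \
        + b.data[None, :, None, None]

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Cout)
        out = [(w, (cols.T @ g2).T.reshape(Cout, Cin, kh, kw)),
               (b, g.sum(axis=(0, 2, 3)))]
        if x.requires_grad:
            gcols = (g2 @ w2.T).reshape(B, Ho, Wo, Cin, kh, kw)
            gxp = _scatter_cols(gcols, xp.shape, stride)
            out.append((x, gxp[:, :, pt:pt + H, pl:pl + W]))
        return tuple(out)

    return Tensor._result(np.ascontiguousarray(out_data), (x, w, b), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2,
                     padding: tuple = (1, 2, 1, 2)) -> Tensor:
    """x: (B, Cin, H, W); w: (Cin, Cout, kh, kw); b: (Cout,)."""
    pl, pr, pt, pb = padding
    B, Cin, H, W = x.data.shape
    Cin_w, Cout, kh, kw = w.data.shape
    if Cin_w != Cin:
        raise ValueError(f"conv_transpose2d channel mismatch: input has {Cin}, weight expects {Cin_w}")
    Ho = conv_transpose_output_size(H, kh, stride, pt, pb)
    Wo = conv_transpose_output_size(W, kw, stride, pl, pr)
    Hp, Wp = Ho + pt + pb, Wo + pl + pr

    x2 = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(B * H * W, Cin)
    w2 = w.data.reshape(Cin, Cout * kh * kw)
    cols = (x2 @ w2).reshape(B, H, W, Cout, kh, kw)
    out_p = _scatter_cols(cols, (B, Cout, Hp, Wp), stride)
    out_data = out_p[:, :, pt:pt + Ho, pl:pl + Wo] + b.data[None, :, None, None]

    def backward(g):
        gp = np.pad(g, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        gcols = _gather_cols(gp, kh, kw, stride).reshape(B * H * W, Cout * kh * kw)
        gx = (gcols @ w2.T).reshape(B, H, W, Cin).transpose(0, 3, 1, 2)
        gw = (x2.T @ gcols).reshape(Cin, Cout, kh, kw)
        gb = g.sum(axis=(0, 2, 3))
        return ((x, np.ascontiguousarray(gx)), (w, gw), (b, gb))

    return Tensor._result(np.ascontiguousarray(out_data), (x, w, b), backward)
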