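"""im2col-based 3D convolution primitives (forward and gradients).

Volumes are laid out (batch, channel, depth, height, width).  Convolution is
expressed as one matrix product against an im2col patch matrix; the data
gradient scatters back with a small loop over kernel offsets, which keeps the
inner work inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv3d_out_shape(in_shape, k: int, stride: int, pad: int):
    return tuple((d + 2 * pad - k) // stride + 1 for d in in_shape)


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, out_shape, padded_shape).

    ``cols`` has one row per output voxel, columns ordered (channel, kd, kh, kw).
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    v = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    v = v[:, :, ::stride, ::stride, ::stride]
    n, c, do, ho, wo = v.shape[:5]
    v = v.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    cols = np.ascontiguousarray(v).reshape(n * do * ho * wo, c * k ** 3)
    return cols, (do, ho, wo), x.shape


def col2im(dcols: np.ndarray, padded_shape, out_shape, k: int, stride: int,
           pad: int) -> np.ndarray:
    """Scatter-add patch gradients back to the (unpadded) input gradient."""
    n, c = padded_shape[0], padded_shape[1]
    do, ho, wo = out_shape
    d = dcols.reshape(n, do, ho, wo, c, k, k, k)
    dxp = np.zeros(padded_shape)
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                dxp[:, :, a:a + stride * do:stride,
                    b:b + stride * ho:stride,
                    cc:cc + stride * wo:stride] += d[..., a, b, cc].transpose(0, 4, 1, 2, 3)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return dxp


def conv3d_forward(x, w_mat, bias, k, stride, pad):
    """w_mat: (cin*k^3, cout).  Returns (out, cache)."""
    cols, out_sp, padded_shape = im2col(x, k, stride, pad)
    out = cols @ w_mat
    if bias is not None:
        out += bias
    n = x.shape[0]
    cout = w_mat.shape[1]
    out = out.reshape(n, *out_sp, cout).transpose(0, 4, 1, 2, 3)
    out = np.ascontiguousarray(out)
    cache = (cols, out_sp, padded_shape, x.shape)
    return out, cache


def conv3d_backward(grad_out, w_mat, cache, k, stride, pad, need_dx=True):
    """Returns (dx, dw_mat, dbias)."""
    cols, out_sp, padded_shape, x_shape = cache
    n, cout = grad_out.shape[0], grad_out.shape[1]
    gf = np.ascontiguousarray(grad_out.transpose(0, 2, 3, 4, 1)).reshape(-1, cout)
    dw = cols.T @ gf
    db = gf.sum(axis=0)
    dx = None
    if need_dx:
        dcols = gf @ w_mat.T
        dx = col2im(dcols, padded_shape, out_sp, k, stride, pad)
    return dx, dw, db


def zero_stuff(x: np.ndarray, stride: int, output_padding) -> np.ndarray:
    """Insert ``stride - 1`` zeros between voxels (transposed-conv upsampling).

    ``output_padding`` may be a scalar or a per-axis triple; it appends extra
    trailing zeros so odd target sizes are reachable.
    """
    n, c, d, h, w = x.shape
    s = stride
    op = np.broadcast_to(np.asarray(output_padding), (3,))
    out = np.zeros((n, c, (d - 1) * s + 1 + int(op[0]),
                    (h - 1) * s + 1 + int(op[1]),
                    (w - 1) * s + 1 + int(op[2])))
    out[:, :, ::s, ::s, ::s] = x
    return out


def trilinear_resize(vol: np.ndarray, target_shape) -> np.ndarray:
    """Resize a 3-axis array with trilinear interpolation (align-corners-free)."""
    from scipy import ndimage

    factors = [t / s for t, s in zip(target_shape, vol.shape)]
    out = ndimage.zoom(vol, factors, order=1, grid_mode=True, mode="nearest")
    # zoom can be off by one voxel on awkward factors; enforce the contract
    if out.shape != tuple(target_shape):  # pragma: no cover - defensive
        out = out[tuple(slice(0, t) for t in target_shape)]
    return out
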