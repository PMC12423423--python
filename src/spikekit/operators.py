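"""Reference forward passes of deformable convolution and scaled attention.

Elongated, variably sized targets are poorly served by a rigid square
sampling grid; deformable convolution displaces each kernel tap by a
per-position 2D offset, sampling the input with bilinear interpolation so
the receptive field can follow the object shape. Scaled dot-product
attention re-weights features by query-key similarity, softmax(Q K^T /
sqrt(d)) V.

These are plain numpy forward passes meant for verification and
documentation of the operator semantics: offsets and weights are inputs,
nothing is learned, and there is no batching, stride or multi-head support.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bilinear_sample", "deformable_conv2d", "scaled_dot_product_attention"]


def bilinear_sample(fm: np.ndarray, x: float, y: float) -> np.ndarray:
    """Bilinearly interpolated per-channel value of an H x W x C grid at (x, y).

    Grid points sit at integer coordinates (x = column, y = row);
    contributions from outside the grid are zero (zero padding).
    """
    fm = np.asarray(fm, dtype=float)
    if fm.ndim == 2:
        fm = fm[:, :, None]
    H, W, C = fm.shape
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    out = np.zeros(C, dtype=float)
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            xi, yi = x0 + dx, y0 + dy
            wgt = wx * wy
            if wgt != 0.0 and 0 <= xi < W and 0 <= yi < H:
                out += wgt * fm[yi, xi, :]
    return out


def deformable_conv2d(fm: np.ndarray, kernel: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Deformable 2D convolution, stride 1, zero padding, extent preserved.

    Parameters
    ----------
    fm : H x W x C_in input feature map.
    kernel : k x k x C_in x C_out weights (square kernel, odd k).
    offsets : H x W x k x k x 2 per-output-position, per-tap (dx, dy)
        displacements in pixels. With all offsets zero the result equals a
        direct (correlation-style) convolution.

    Returns
    -------
    H x W x C_out output feature map.
    """
    fm = np.asarray(fm, dtype=float)
    if fm.ndim == 2:
        fm = fm[:, :, None]
    kernel = np.asarray(kernel, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    H, W, C_in = fm.shape
    if kernel.ndim != 4 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError(f"kernel must be k x k x C_in x C_out, got shape {kernel.shape}")
    k = kernel.shape[0]
    if kernel.shape[2] != C_in:
        raise ValueError(f"kernel C_in {kernel.shape[2]} != input channels {C_in}")
    if offsets.shape != (H, W, k, k, 2):
        raise ValueError(
            f"offsets must have shape {(H, W, k, k, 2)}, got {offsets.shape}"
        )
    C_out = kernel.shape[3]
    half = (k - 1) // 2
    out = np.zeros((H, W, C_out), dtype=float)
    for oy in range(H):
        for ox in range(W):
            acc = np.zeros(C_out, dtype=float)
            for ky in range(k):
                for kx in range(k):
                    dx, dy = offsets[oy, ox, ky, kx]
                    sx = ox + kx - half + dx
                    sy = oy + ky - half + dy
                    val = bilinear_sample(fm, sx, sy)  # C_in vector
                    acc += val @ kernel[ky, kx]  # (C_in) @ (C_in, C_out)
            out[oy, ox] = acc
    return out


def scaled_dot_product_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, return_weights: bool = False
):
    """softmax(Q K^T / sqrt(d)) V with a max-subtracted, numerically stable softmax.

    Q is n_q x d, K is n_k x d, V is n_k x d_v; returns n_q x d_v outputs
    (and the n_q x n_k weight matrix when ``return_weights``). Each weight
    row sums to 1.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    K = np.atleast_2d(np.asarray(K, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d = Q.shape[1]
    if d == 0 or K.shape[1] != d:
        raise ValueError(f"query/key inner dimension mismatch or zero: {Q.shape}, {K.shape}")
    if V.shape[0] != K.shape[0]:
        raise ValueError(f"keys and values disagree on n_k: {K.shape}, {V.shape}")
    logits = (Q @ K.T) / np.sqrt(d)
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    out = w @ V
    if return_weights:
        return out, w
    return out
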