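"""Numba-compiled direct 3D convolution kernels.

Shift-and-add loops with a contiguous innermost axis so fastmath can
vectorize; no im2col buffers, so memory stays at the size of the
activations. All kernels implement *valid* (unpadded) stride-1 cross
correlation, matching the layer semantics in :mod:`rnaqa._nn`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3d_forward(x, w, b):
    """x (B,C,D,H,W), w (O,C,k,k,k), b (O) -> y (B,O,D',H',W')."""
    B, C, D, H, Wd = x.shape
    O, _, k, _, _ = w.shape
    Do, Ho, Wo = D - k + 1, H - k + 1, Wd - k + 1
    y = np.empty((B, O, Do, Ho, Wo), dtype=x.dtype)
    for bi in range(B):
        for o in range(O):
            acc = np.full((Do, Ho, Wo), b[o], dtype=x.dtype)
            for c in range(C):
                for dx in range(k):
                    for dy in range(k):
                        for dz in range(k):
                            wv = w[o, c, dx, dy, dz]
                            for i in range(Do):
                                for j in range(Ho):
                                    for l in range(Wo):
                                        acc[i, j, l] += wv * x[bi, c, dx + i, dy + j, dz + l]
            y[bi, o] = acc
    return y


@njit(cache=True, fastmath=True)
def conv3d_backward_w(x, gy, k):
    """Weight gradient: gw (O,C,k,k,k), gb (O)."""
    B, C, D, H, Wd = x.shape
    O = gy.shape[1]
    Do, Ho, Wo = gy.shape[2], gy.shape[3], gy.shape[4]
    gw = np.zeros((O, C, k, k, k), dtype=x.dtype)
    gb = np.zeros(O, dtype=x.dtype)
    for bi in range(B):
        for o in range(O):
            for c in range(C):
                for dx in range(k):
                    for dy in range(k):
                        for dz in range(k):
                            s = 0.0
                            for i in range(Do):
                                for j in range(Ho):
                                    for l in range(Wo):
                                        s += gy[bi, o, i, j, l] * x[bi, c, dx + i, dy + j, dz + l]
                            gw[o, c, dx, dy, dz] += s
            for i in range(Do):
                for j in range(Ho):
                    for l in range(Wo):
                        gb[o] += gy[bi, o, i, j, l]
    return gw, gb


@njit(cache=True, fastmath=True)
def conv3d_backward_x(gy, w, D, H, Wd):
    """Input gradient: gx (B,C,D,H,W) given gy (B,O,D',H',W')."""
    B, O, Do, Ho, Wo = gy.shape
    C, k = w.shape[1], w.shape[2]
    gx = np.zeros((B, C, D, H, Wd), dtype=gy.dtype)
    for bi in range(B):
        for o in range(O):
            for c in range(C):
                for dx in range(k):
                    for dy in range(k):
                        for dz in range(k):
                            wv = w[o, c, dx, dy, dz]
                            for i in range(Do):
                                for j in range(Ho):
                                    for l in range(Wo):
                                        gx[bi, c, dx + i, dy + j, dz + l] += wv * gy[bi, o, i, j, l]
    return gx
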