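"""Numba kernels for the depth-wise 3x3 convolution.

The depth-wise pass is bandwidth-bound: a vectorized numpy formulation
needs nine full passes over the feature maps, whereas these fused
kernels read each pixel once.  ``dw_correlate`` doubles as the input
gradient by passing the 180°-flipped kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def dw_correlate(xp, w, out):
    """out[n,c] = 2-D correlation of padded xp[n,c] with w[c] (3x3, 'valid')."""
    n, c, _, _ = xp.shape
    h, wd = out.shape[2], out.shape[3]
    for nn in range(n):
        for cc in range(c):
            w00, w01, w02 = w[cc, 0, 0], w[cc, 0, 1], w[cc, 0, 2]
            w10, w11, w12 = w[cc, 1, 0], w[cc, 1, 1], w[cc, 1, 2]
            w20, w21, w22 = w[cc, 2, 0], w[cc, 2, 1], w[cc, 2, 2]
            for hh in range(h):
                for ww in range(wd):
                    out[nn, cc, hh, ww] = (
                        w00 * xp[nn, cc, hh, ww]
                        + w01 * xp[nn, cc, hh, ww + 1]
                        + w02 * xp[nn, cc, hh, ww + 2]
                        + w10 * xp[nn, cc, hh + 1, ww]
                        + w11 * xp[nn, cc, hh + 1, ww + 1]
                        + w12 * xp[nn, cc, hh + 1, ww + 2]
                        + w20 * xp[nn, cc, hh + 2, ww]
                        + w21 * xp[nn, cc, hh + 2, ww + 1]
                        + w22 * xp[nn, cc, hh + 2, ww + 2]
                    )


@njit(fastmath=True, cache=True)
def dw_weight_grad(xp, g, dw):
    """dw[c,i,j] = sum over (n,h,w) of xp[n,c,h+i,w+j] * g[n,c,h,w]."""
    n, c, _, _ = xp.shape
    h, wd = g.shape[2], g.shape[3]
    for cc in range(c):
        for i in range(3):
            for j in range(3):
                dw[cc, i, j] = 0.0
    for nn in range(n):
        for cc in range(c):
            a00 = a01 = a02 = a10 = a11 = a12 = a20 = a21 = a22 = 0.0
            for hh in range(h):
                for ww in range(wd):
                    gv = g[nn, cc, hh, ww]
                    a00 += gv * xp[nn, cc, hh, ww]
                    a01 += gv * xp[nn, cc, hh, ww + 1]
                    a02 += gv * xp[nn, cc, hh, ww + 2]
                    a10 += gv * xp[nn, cc, hh + 1, ww]
                    a11 += gv * xp[nn, cc, hh + 1, ww + 1]
                    a12 += gv * xp[nn, cc, hh + 1, ww + 2]
                    a20 += gv * xp[nn, cc, hh + 2, ww]
                    a21 += gv * xp[nn, cc, hh + 2, ww + 1]
                    a22 += gv * xp[nn, cc, hh + 2, ww + 2]
            dw[cc, 0, 0] += a00
            dw[cc, 0, 1] += a01
            dw[cc, 0, 2] += a02
            dw[cc, 1, 0] += a10
            dw[cc, 1, 1] += a11
            dw[cc, 1, 2] += a12
            dw[cc, 2, 0] += a20
            dw[cc, 2, 1] += a21
            dw[cc, 2, 2] += a22
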