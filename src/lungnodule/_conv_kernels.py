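"""Strip-blocked 3-D convolution kernels (numba).

The im2col patch for one output row strip (all kernel taps x one row of
output voxels) is small enough to stay cache-resident, so each strip
costs one in-cache gather plus one small BLAS matmul instead of a
volume-sized column-matrix round trip through RAM.  The forward and
backward kernels share the gather layout; the backward computes the
weight gradient and the (padded) input gradient in one pass.

Arrays are float32, channels-first, C-contiguous; padding is applied by
the caller.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    NUMBA = True
except Exception:  # pragma: no cover
    NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap


@njit(cache=True, fastmath=True)
def conv3d_forward(xp, Wm, b, kd, kh, kw, sd, sh, sw, y):
    """xp (N,C,Dp,Hp,Wp) padded input; Wm (O, C*kd*kh*kw); y (N,O,Do,Ho,Wo) out."""
    N, C = xp.shape[0], xp.shape[1]
    O = Wm.shape[0]
    Do, Ho, Wo = y.shape[2], y.shape[3], y.shape[4]
    K = C * kd * kh * kw
    patch = np.empty((K, Wo), dtype=xp.dtype)
    for n in range(N):
        for od in range(Do):
            for oh in range(Ho):
                r = 0
                for c in range(C):
                    for a in range(kd):
                        for bb in range(kh):
                            src = xp[n, c, od * sd + a, oh * sh + bb]
                            for e in range(kw):
                                for t in range(Wo):
                                    patch[r, t] = src[e + sw * t]
                                r += 1
                out = np.dot(Wm, patch)
                for o in range(O):
                    for t in range(Wo):
                        y[n, o, od, oh, t] = out[o, t] + b[o]


@njit(cache=True, fastmath=True)
def conv3d_backward(xp, Wm, gy, kd, kh, kw, sd, sh, sw, gxp, gWT):
    """Accumulate gWT (C*K, O) and gxp (padded-input gradient) from gy."""
    N, C = xp.shape[0], xp.shape[1]
    O, K = Wm.shape
    Do, Ho, Wo = gy.shape[2], gy.shape[3], gy.shape[4]
    WmT = np.ascontiguousarray(Wm.T)
    patch = np.empty((K, Wo), dtype=xp.dtype)
    gys = np.empty((O, Wo), dtype=xp.dtype)
    gyT = np.empty((Wo, O), dtype=xp.dtype)
    for n in range(N):
        for od in range(Do):
            for oh in range(Ho):
                for o in range(O):
                    for t in range(Wo):
                        v = gy[n, o, od, oh, t]
                        gys[o, t] = v
                        gyT[t, o] = v
                r = 0
                for c in range(C):
                    for a in range(kd):
                        for bb in range(kh):
                            src = xp[n, c, od * sd + a, oh * sh + bb]
                            for e in range(kw):
                                for t in range(Wo):
                                    patch[r, t] = src[e + sw * t]
                                r += 1
                gWT += np.dot(patch, gyT)
                gpatch = np.dot(WmT, gys)
                r = 0
                for c in range(C):
                    for a in range(kd):
                        for bb in range(kh):
                            dst = gxp[n, c, od * sd + a, oh * sh + bb]
                            for e in range(kw):
                                for t in range(Wo):
                                    dst[e + sw * t] += gpatch[r, t]
                                r += 1
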