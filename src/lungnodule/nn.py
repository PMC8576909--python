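"""Minimal 3-D convolutional network engine.

Implements the handful of layers the segmentation and classification
networks need — 3-D convolution, transposed convolution, max pooling,
instance normalization, ReLU/sigmoid, a linear head — as numpy modules
with explicit, hand-derived backward passes, plus Adam and Xavier
initialization.  Arrays are float32 in (N, C, D, H, W) layout with axes
(batch, channel, axial, coronal, sagittal).

Every backward pass is validated against central finite differences in
the test suite; the engine is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from . import _conv_kernels as _kern

DTYPE = np.float32


def xavier_uniform(shape, fan_in, fan_out, rng):
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _triple(v):
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 tuple, got {v!r}")
    return t


class Module:
    """Base class: parameters/grads are dicts of numpy arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._children: list[Module] = []

    def add_child(self, m: "Module") -> "Module":
        self._children.append(m)
        return m

    def parameters(self):
        """Yield (module, key) pairs for every trainable array."""
        for k in self.params:
            yield self, k
        for c in self._children:
            yield from c.parameters()

    def n_parameters(self) -> int:
        return sum(m.params[k].size for m, k in self.parameters())

    def modules(self):
        yield self
        for c in self._children:
            yield from c.modules()

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

class Conv3d(Module):
    """3-D convolution via im2col + matmul.

    Kernel offsets are gathered with strided slices (at most k^3
    iterations of vectorized copies), so the hot path is a single BLAS
    matmul per call.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = int(in_ch), int(out_ch)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        k = int(np.prod(self.kernel))
        rng = rng or np.random.default_rng()
        self.params["W"] = xavier_uniform(
            (self.out_ch, self.in_ch) + self.kernel,
            fan_in=self.in_ch * k, fan_out=self.out_ch * k, rng=rng)
        self.params["b"] = np.zeros(self.out_ch, dtype=DTYPE)
        self._cache = None

    def out_shape(self, spatial):
        return tuple(
            (spatial[i] + 2 * self.padding[i] - self.kernel[i]) // self.stride[i] + 1
            for i in range(3))

    def _im2col(self, xp, out_sp):
        # column matrix built directly in (N*P, C*K) matmul layout
        n, c = xp.shape[:2]
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        do, ho, wo = out_sp
        col = np.empty((n, do, ho, wo, c, kd, kh, kw), dtype=DTYPE)
        for a in range(kd):
            for b in range(kh):
                for e in range(kw):
                    col[..., a, b, e] = np.moveaxis(xp[
                        :, :,
                        a:a + sd * (do - 1) + 1:sd,
                        b:b + sh * (ho - 1) + 1:sh,
                        e:e + sw * (wo - 1) + 1:sw], 1, -1)
        return col.reshape(n * do * ho * wo, c * kd * kh * kw)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c = x.shape[:2]
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        out_sp = self.out_shape(x.shape[2:])
        if min(out_sp) < 1:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} too small for kernel "
                f"{self.kernel} stride {self.stride}")
        wm = np.ascontiguousarray(self.params["W"].reshape(self.out_ch, -1))
        y = np.empty((n, self.out_ch) + out_sp, dtype=DTYPE)
        if _kern.NUMBA:
            _kern.conv3d_forward(xp, wm, self.params["b"],
                                 *self.kernel, *self.stride, y)
        else:  # pure-numpy fallback
            mat = self._im2col(xp, out_sp)
            ym = mat @ wm.T + self.params["b"]
            y[:] = ym.reshape((n,) + out_sp + (self.out_ch,)).transpose(0, 4, 1, 2, 3)
        self._cache = (xp, x.shape, out_sp)
        return y

    def backward(self, gy):
        xp, x_shape, out_sp = self._cache
        n = x_shape[0]
        do, ho, wo = out_sp
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        self.grads["b"] = gy.sum(axis=(0, 2, 3, 4))
        gxp = np.zeros(xp.shape, dtype=DTYPE)
        wm = np.ascontiguousarray(self.params["W"].reshape(self.out_ch, -1))
        if _kern.NUMBA:
            gwt = np.zeros((wm.shape[1], self.out_ch), dtype=DTYPE)
            _kern.conv3d_backward(xp, wm, gy, *self.kernel, *self.stride, gxp, gwt)
            self.grads["W"] = np.ascontiguousarray(gwt.T).reshape(self.params["W"].shape)
        else:
            mat = self._im2col(xp, out_sp)
            gmat_out = gy.transpose(0, 2, 3, 4, 1).reshape(
                n * do * ho * wo, self.out_ch)
            self.grads["W"] = (gmat_out.T @ mat).reshape(self.params["W"].shape)
            gcol = (gmat_out @ wm).reshape(n, do, ho, wo, self.in_ch, *self.kernel)
            kd, kh, kw = self.kernel
            sd, sh, sw = self.stride
            for a in range(kd):
                for b in range(kh):
                    for e in range(kw):
                        gxp[:, :,
                            a:a + sd * (do - 1) + 1:sd,
                            b:b + sh * (ho - 1) + 1:sh,
                            e:e + sw * (wo - 1) + 1:sw] += np.moveaxis(
                                gcol[..., a, b, e], -1, 1)
        pd, ph, pw = self.padding
        d, h, w = x_shape[2:]
        return gxp[:, :, pd:pd + d, ph:ph + h, pw:pw + w]


class ConvTranspose3d(Module):
    """Transposed 3-D convolution with kernel 2, stride 2 (the decoder
    upsampler): every input voxel expands into a learned 2x2x2 block."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = int(in_ch), int(out_ch)
        rng = rng or np.random.default_rng()
        self.params["W"] = xavier_uniform(
            (self.in_ch, self.out_ch, 2, 2, 2),
            fan_in=self.in_ch * 8, fan_out=self.out_ch * 8, rng=rng)
        self.params["b"] = np.zeros(self.out_ch, dtype=DTYPE)
        self._cache = None

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, d, h, w = x.shape
        y = np.einsum("nidhw,ioabc->nodahbwc", x, self.params["W"],
                      optimize=True)
        y = y.reshape(n, self.out_ch, 2 * d, 2 * h, 2 * w)
        y += self.params["b"][None, :, None, None, None]
        self._cache = x
        return y

    def backward(self, gy):
        x = self._cache
        n, c, d, h, w = x.shape
        g = gy.reshape(n, self.out_ch, d, 2, h, 2, w, 2)
        self.grads["W"] = np.einsum("nidhw,nodahbwc->ioabc", x, g, optimize=True)
        self.grads["b"] = gy.sum(axis=(0, 2, 3, 4))
        return np.einsum("nodahbwc,ioabc->nidhw", g, self.params["W"],
                         optimize=True)


class MaxPool3d(Module):
    """Non-overlapping 2x2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial shape {(d, h, w)} not divisible by 2")
        blk = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = blk.max(axis=(3, 5, 7))
        self._cache = (blk, y)
        return y

    def backward(self, gy):
        blk, y = self._cache
        mask = (blk == y[:, :, :, None, :, None, :, None])
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (gy[:, :, :, None, :, None, :, None] / counts)
        n, c = blk.shape[:2]
        d, h, w = blk.shape[2] * 2, blk.shape[4] * 2, blk.shape[6] * 2
        return g.reshape(n, c, d, h, w)


class InstanceNorm3d(Module):
    """Per-(sample, channel) standardization over the spatial axes.

    No affine parameters; epsilon 1e-5.
    """

    def __init__(self, eps=1e-5):
        super().__init__()
        self.eps = eps
        self._cache = None

    def forward(self, x):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat.astype(DTYPE), inv.astype(DTYPE))
        return self._cache[0]

    def backward(self, gy):
        xhat, inv = self._cache
        m1 = gy.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (gy * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return (gy - m1 - xhat * m2) * inv


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, gy):
        return np.where(self._mask, gy, 0).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = xavier_uniform(
            (in_features, out_features), in_features, out_features, rng)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)
        self._cache = None

    def forward(self, x):
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        x = self._cache
        self.grads["W"] = x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def log_softmax(z):
    z = np.asarray(z, dtype=np.float64)
    m = z.max(axis=-1, keepdims=True)
    e = z - m
    return e - np.log(np.exp(e).sum(axis=-1, keepdims=True))


class Adam:
    """Adam optimizer over a module tree's (params, grads) dicts."""

    def __init__(self, model: Module, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {}
        for i, (m, k) in enumerate(model.parameters()):
            self.state[i] = (np.zeros_like(m.params[k]),
                             np.zeros_like(m.params[k]))

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (m, k) in enumerate(self.model.parameters()):
            g = m.grads.get(k)
            if g is None:
                continue
            mo, vo = self.state[i]
            mo *= self.b1
            mo += (1 - self.b1) * g
            vo *= self.b2
            vo += (1 - self.b2) * g * g
            m.params[k] -= self.lr * (mo / b1t) / (np.sqrt(vo / b2t) + self.eps)

    def zero_grad(self):
        for m, k in self.model.parameters():
            m.grads.pop(k, None)
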