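"""Modified 3-D ResNet50 for benign/malignant nodule classification.

Three departures from the stock 2-D ResNet50, motivated by small,
spatially rich lesions in thin 16 x 48 x 48 ROIs:

* every convolution is 3-D;
* kernels are reduced where a large receptive field would mostly see
  padding: the 7x7 stem becomes 3x3x3, and the middle convolutions of
  the last two stages use 1x3x3 (sparing the short axial axis);
* there is no max pooling anywhere - all downsampling is by strided
  convolution, with stage strides (1,1,1), (1,2,2), (2,2,2), (2,2,2),
  leaving a 4x6x6 final grid for the default ROI.

Stages hold the usual bottleneck blocks (1x1x1 / 3x3x3 / 1x1x1,
expansion 4) with counts (3, 4, 6, 3).  Normalization is instance
normalization (batch-size robust); a global average pool and a 2-way
linear head emit log-probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .volume import ClassProbabilities


@dataclass(frozen=True)
class ClsNetworkSpec:
    stem_channels: int = 64
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    block_counts: tuple[int, ...] = (3, 4, 6, 3)
    expansion: int = 4
    stem_kernel: tuple[int, int, int] = (3, 3, 3)
    #: stage indices whose middle conv kernel is reduced to 1x3x3
    reduced_kernel_stages: tuple[int, ...] = (2, 3)
    stage_strides: tuple[tuple[int, int, int], ...] = (
        (1, 1, 1), (1, 2, 2), (2, 2, 2), (2, 2, 2))
    n_classes: int = 2

    def validate(self):
        if not (len(self.stage_widths) == len(self.block_counts) == len(self.stage_strides)):
            raise ValueError("stage_widths, block_counts, stage_strides must align")
        if any(w < 1 for w in self.stage_widths) or any(b < 1 for b in self.block_counts):
            raise ValueError("widths and block counts must be positive")

    def scaled(self, factor: float) -> "ClsNetworkSpec":
        """Width-scaled variant for CPU-sized experiments."""
        from dataclasses import replace
        return replace(
            self,
            stem_channels=max(1, int(self.stem_channels * factor)),
            stage_widths=tuple(max(1, int(w * factor)) for w in self.stage_widths),
        )

    def total_stride(self):
        s = np.ones(3, dtype=int)
        for st in self.stage_strides:
            s *= st
        return tuple(int(v) for v in s)


class Bottleneck(nn.Module):
    """1x1x1 reduce -> kxkxk (strided in the first block) -> 1x1x1 expand."""

    def __init__(self, in_ch, width, out_ch, mid_kernel, stride, rng):
        super().__init__()
        pad = tuple((k - 1) // 2 for k in mid_kernel)
        self.conv1 = self.add_child(nn.Conv3d(in_ch, width, 1, rng=rng))
        self.in1 = self.add_child(nn.InstanceNorm3d())
        self.r1 = self.add_child(nn.ReLU())
        self.conv2 = self.add_child(
            nn.Conv3d(width, width, mid_kernel, stride=stride, padding=pad, rng=rng))
        self.in2 = self.add_child(nn.InstanceNorm3d())
        self.r2 = self.add_child(nn.ReLU())
        self.conv3 = self.add_child(nn.Conv3d(width, out_ch, 1, rng=rng))
        self.in3 = self.add_child(nn.InstanceNorm3d())
        self.has_proj = (in_ch != out_ch) or (tuple(stride) != (1, 1, 1))
        if self.has_proj:
            self.proj = self.add_child(nn.Conv3d(in_ch, out_ch, 1, stride=stride, rng=rng))
            self.projin = self.add_child(nn.InstanceNorm3d())
        self.rout = self.add_child(nn.ReLU())

    def forward(self, x):
        m = self.in3(self.conv3(self.r2(self.in2(self.conv2(
            self.r1(self.in1(self.conv1(x))))))))
        i = self.projin(self.proj(x)) if self.has_proj else x
        self._identity_passthrough = not self.has_proj
        return self.rout(m + i)

    def backward(self, g):
        g = self.rout.backward(g)
        gm = self.conv1.backward(self.in1.backward(self.r1.backward(
            self.conv2.backward(self.in2.backward(self.r2.backward(
                self.conv3.backward(self.in3.backward(g))))))))
        gi = self.proj.backward(self.projin.backward(g)) if self.has_proj else g
        return gm + gi


class ResNet3D50(nn.Module):
    def __init__(self, spec: ClsNetworkSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        sk = spec.stem_kernel
        self.stem = self.add_child(nn.Conv3d(
            1, spec.stem_channels, sk, padding=tuple((k - 1) // 2 for k in sk), rng=rng))
        self.stem_in = self.add_child(nn.InstanceNorm3d())
        self.stem_relu = self.add_child(nn.ReLU())
        self.blocks: list[Bottleneck] = []
        in_ch = spec.stem_channels
        for si, (w, n, stride) in enumerate(zip(
                spec.stage_widths, spec.block_counts, spec.stage_strides)):
            out_ch = w * spec.expansion
            mid_kernel = (1, 3, 3) if si in spec.reduced_kernel_stages else (3, 3, 3)
            for bi in range(n):
                self.blocks.append(self.add_child(Bottleneck(
                    in_ch, w, out_ch, mid_kernel,
                    stride if bi == 0 else (1, 1, 1), rng)))
                in_ch = out_ch
        self.fc = self.add_child(nn.Linear(in_ch, spec.n_classes, rng=rng))

    def forward_logits(self, x):
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        ts = self.spec.total_stride()
        if any(s < t for s, t in zip(x.shape[2:], ts)):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} smaller than the total "
                f"stride product {ts}; use a larger ROI or smaller strides")
        x = self.stem_relu(self.stem_in(self.stem(x)))
        for b in self.blocks:
            x = b(x)
        self._gap_spatial = x.shape[2:]
        feat = x.mean(axis=(2, 3, 4))
        return self.fc(feat)

    def forward(self, x):
        """Log-probabilities (N, 2): columns (benign, malignant)."""
        return nn.log_softmax(self.forward_logits(x))

    def backward(self, g_logits):
        g = self.fc.backward(np.asarray(g_logits, dtype=nn.DTYPE))
        d, h, w = self._gap_spatial
        g = np.broadcast_to(
            g[:, :, None, None, None] / (d * h * w),
            g.shape + (d, h, w)).astype(nn.DTYPE)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return self.stem.backward(self.stem_in.backward(self.stem_relu.backward(g)))

    def n_pooling_layers(self) -> int:
        """Max-pooling layers in the model (global average excluded)."""
        return sum(isinstance(m, nn.MaxPool3d) for m in self.modules())


def build_classifier(spec: ClsNetworkSpec = ClsNetworkSpec(), seed: int = 0) -> ResNet3D50:
    return ResNet3D50(spec, seed=seed)


def classify_roi(model: ResNet3D50, roi) -> ClassProbabilities:
    """Classify one grayscale 16x48x48 ROI in [0,1]."""
    v = np.asarray(roi, dtype=np.float32)
    if v.ndim != 3:
        raise ValueError(f"expected a 3-D ROI, got shape {v.shape}")
    logp = model.forward(v)[0]
    p = np.exp(logp)
    p = p / p.sum()
    return ClassProbabilities(p_benign=float(p[0]), p_malignant=float(p[1]))
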