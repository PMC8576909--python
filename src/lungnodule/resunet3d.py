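"""3-D Res U-Net for volumetric nodule segmentation.

Encoder-decoder with skip concatenation where every conv pair is a
residual unit: mapping path Conv3x3x3 -> IN -> ReLU -> Conv3x3x3 -> IN,
identity path Conv1x1x1 -> IN -> ReLU (present in every unit so channel
counts always match), elementwise sum, ReLU.  Four down-sampling stages
(residual unit then 2x2x2 max pool) double the channels each time along
the ladder 8-16-32-64 into a 128-channel bottleneck; four decoder stages
(transposed conv k=2 s=2 -> IN -> ReLU, concatenate the matching
encoder feature, residual unit halving the channels) restore the input
resolution; a 1x1x1 conv + sigmoid emits the probability map.  For a
1 x 48 x 192 x 192 input the bottleneck feature map is 128 x 3 x 12 x 12.

The channel ladder is configurable so scaled-down variants exist for
CPU-sized experiments; the default equals the reference architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .volume import BinaryMask


@dataclass(frozen=True)
class SegNetworkSpec:
    in_channels: int = 1
    channels: tuple[int, ...] = (8, 16, 32, 64)
    bottleneck: int = 128

    def validate(self):
        if len(self.channels) < 1 or any(c < 1 for c in self.channels):
            raise ValueError(f"bad channel ladder {self.channels}")
        if self.bottleneck < 1:
            raise ValueError("bottleneck channels must be >= 1")

    @property
    def depth(self) -> int:
        return len(self.channels)


QUARTER_SPEC = SegNetworkSpec(channels=(2, 4, 8, 16), bottleneck=32)


class ResidualUnit(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv1 = self.add_child(nn.Conv3d(in_ch, out_ch, 3, padding=1, rng=rng))
        self.in1 = self.add_child(nn.InstanceNorm3d())
        self.relu1 = self.add_child(nn.ReLU())
        self.conv2 = self.add_child(nn.Conv3d(out_ch, out_ch, 3, padding=1, rng=rng))
        self.in2 = self.add_child(nn.InstanceNorm3d())
        self.idconv = self.add_child(nn.Conv3d(in_ch, out_ch, 1, rng=rng))
        self.idin = self.add_child(nn.InstanceNorm3d())
        self.idrelu = self.add_child(nn.ReLU())
        self.relu_out = self.add_child(nn.ReLU())

    def forward(self, x):
        m = self.in2(self.conv2(self.relu1(self.in1(self.conv1(x)))))
        i = self.idrelu(self.idin(self.idconv(x)))
        return self.relu_out(m + i)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gm = self.conv1.backward(self.in1.backward(self.relu1.backward(
            self.conv2.backward(self.in2.backward(g)))))
        gi = self.idconv.backward(self.idin.backward(self.idrelu.backward(g)))
        return gm + gi


class UNet3D(nn.Module):
    def __init__(self, spec: SegNetworkSpec, seed: int = 0, head_bias: float = -4.0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels
        self.enc_units, self.pools = [], []
        c_in = spec.in_channels
        for c in ch:
            self.enc_units.append(self.add_child(ResidualUnit(c_in, c, rng)))
            self.pools.append(self.add_child(nn.MaxPool3d()))
            c_in = c
        self.bottle = self.add_child(ResidualUnit(ch[-1], spec.bottleneck, rng))
        self.upconvs, self.up_ins, self.up_relus, self.dec_units = [], [], [], []
        c_in = spec.bottleneck
        for c in reversed(ch):
            self.upconvs.append(self.add_child(nn.ConvTranspose3d(c_in, c, rng=rng)))
            self.up_ins.append(self.add_child(nn.InstanceNorm3d()))
            self.up_relus.append(self.add_child(nn.ReLU()))
            self.dec_units.append(self.add_child(ResidualUnit(2 * c, c, rng)))
            c_in = c
        self.head = self.add_child(nn.Conv3d(ch[0], 1, 1, rng=rng))
        # start from the sparse-foreground prior: nodules occupy ~0.2% of a
        # volume, so the output bias opens at the background log-odds; this
        # keeps the early Dice phase out of its diffuse-prediction stall
        self.head.params["b"][:] = head_bias

    def _check_divisible(self, spatial):
        f = 2 ** self.spec.depth
        bad = [s for s in spatial if s % f]
        if bad:
            pads = {s: (f - s % f) % f for s in spatial}
            raise ValueError(
                f"spatial shape {tuple(spatial)} not divisible by {f}; "
                f"pad by {pads} voxels (per axis) first")

    def forward_logits(self, x):
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        self._check_divisible(x.shape[2:])
        skips = []
        for unit, pool in zip(self.enc_units, self.pools):
            x = unit(x)
            skips.append(x)
            x = pool(x)
        x = self.bottle(x)
        self._skip_channels = []
        for up, ino, relu, unit, skip in zip(
                self.upconvs, self.up_ins, self.up_relus, self.dec_units,
                reversed(skips)):
            x = relu(ino(up(x)))
            self._skip_channels.append(x.shape[1])
            if x.shape[2:] != skip.shape[2:]:
                raise AssertionError("skip/decoder spatial shapes differ")
            x = np.concatenate([x, skip], axis=1)
            x = unit(x)
        return self.head(x)

    def forward(self, x):
        """Probability volume (sigmoid of the logits)."""
        return nn.sigmoid(self.forward_logits(x)).astype(nn.DTYPE)

    def backward(self, g_logits):
        g = self.head.backward(np.asarray(g_logits, dtype=nn.DTYPE))
        skip_grads = [None] * len(self.dec_units)
        for j in range(len(self.dec_units) - 1, -1, -1):
            g = self.dec_units[j].backward(g)
            c_up = self._skip_channels[j]
            g_up, g_skip = g[:, :c_up], g[:, c_up:]
            skip_grads[j] = g_skip
            g = self.upconvs[j].backward(
                self.up_ins[j].backward(self.up_relus[j].backward(g_up)))
        g = self.bottle.backward(g)
        for i in range(len(self.enc_units) - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[len(self.enc_units) - 1 - i]
            g = self.enc_units[i].backward(g)
        return g


def build_segmentation_network(spec: SegNetworkSpec = SegNetworkSpec(),
                               seed: int = 0) -> UNet3D:
    """Xavier-initialized 3-D Res U-Net for the given channel ladder."""
    return UNet3D(spec, seed=seed)


def forward_segment(model: UNet3D, volume) -> np.ndarray:
    """Run inference on one grayscale volume in [0,1]; returns the
    probability volume with the same spatial shape."""
    v = np.asarray(volume, dtype=np.float32)
    if v.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {v.shape}")
    return model.forward(v)[0, 0]


def predict_mask(prob, threshold: float = 0.5) -> BinaryMask:
    """Binarize a probability volume; ties (== threshold) are included."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p = np.asarray(getattr(prob, "values", prob))
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return BinaryMask((p >= threshold).astype(np.uint8))


def shape_table(spec: SegNetworkSpec = SegNetworkSpec(),
                input_shape=(48, 192, 192)):
    """Per-stage (name, channels, spatial shape) records.

    Encoder rows are post-pool, decoder rows post-unit, matching the
    published layer table.  Computed symbolically from the architecture
    contract (spatial halving per stage); `forward` obeys the same rules
    by construction, which the tests cross-check on a scaled variant.
    """
    spec.validate()
    d, h, w = (int(s) for s in input_shape)
    f = 2 ** spec.depth
    if d % f or h % f or w % f:
        raise ValueError(f"input shape {input_shape} not divisible by {f}")
    rows = [("Input", spec.in_channels, (d, h, w))]
    for i, c in enumerate(spec.channels):
        k = 2 ** (i + 1)
        rows.append((f"Encoder{i}", c, (d // k, h // k, w // k)))
    rows.append(("Bottle", spec.bottleneck, (d // f, h // f, w // f)))
    for i, c in enumerate(reversed(spec.channels)):
        k = 2 ** (spec.depth - 1 - i)
        rows.append((f"Decoder{i}", c, (d // k, h // k, w // k)))
    rows.append(("OutputConv", 1, (d, h, w)))
    return rows
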