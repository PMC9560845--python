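"""ResNet-34 feature encoder with five skip taps.

The encoder is the standard ResNet-34 stage layout — 7x7/stride-2 stem with
batch norm and ReLU, 3x3/stride-2 max pool, then residual stages of
[3, 4, 6, 3] basic blocks at widths 64/128/256/512 — with the classifier
head removed. Five taps feed the decoder:

====== ======== ========================
stride channels tap
====== ======== ========================
2      64       stem output (before pool)
4      64       stage-1 output
8      128      stage-2 output
16     256      stage-3 output
32     512      stage-4 output (bottleneck)
====== ======== ========================

For an input of size HxW (divisible by 32) the tap spatial sizes are
exactly H/2, H/4, H/8, H/16 and H/32; e.g. an 800x800 image yields a
25x25x512 bottleneck. The stem tap is taken after the stem convolution and
before max pooling, which is what makes the decoder's final full-resolution
stage line up.

All widths scale jointly through ``width_scale`` (1.0 = full model), so
reduced configurations for desk-scale training keep the same topology.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

#: ResNet-34 residual-stage depths.
STAGE_BLOCKS = (3, 4, 6, 3)
#: Full-width channel plan: stem, stage1..stage4.
FULL_WIDTHS = (64, 64, 128, 256, 512)


class EncoderPyramid(NamedTuple):
    """The five skip-tap feature maps, shallowest first."""

    tap_s2: Tensor
    tap_s4: Tensor
    tap_s8: Tensor
    tap_s16: Tensor
    bottleneck: Tensor

    @property
    def strides(self) -> tuple[int, ...]:
        return (2, 4, 8, 16, 32)


def scaled_widths(width_scale: float) -> tuple[int, ...]:
    """Channel plan under a global width multiplier (minimum 1 per stage)."""
    return tuple(max(1, round(w * width_scale)) for w in FULL_WIDTHS)


def check_divisible(h: int, w: int, stride: int = 32) -> None:
    if h % stride or w % stride:
        raise ValueError(
            f"input size {h}x{w} is not divisible by {stride}; "
            "use mhanet.data.pad_to_stride before encoding"
        )


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity (or 1x1-projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, pad=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, pad=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        identity = x
        h = ag.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return ag.relu(ag.add(h, identity))


class ResNetEncoder(nn.Module):
    """ResNet-34 trunk exposing the five-tap :class:`EncoderPyramid`."""

    def __init__(self, rng: np.random.Generator, width_scale: float = 1.0):
        super().__init__()
        ws = scaled_widths(width_scale)
        self.widths = ws
        self.stem_conv = nn.Conv2d(3, ws[0], 7, rng, stride=2, pad=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(ws[0])
        stages = []
        in_ch = ws[0]
        for si, (blocks, out_ch) in enumerate(zip(STAGE_BLOCKS, ws[1:])):
            mods = []
            for b in range(blocks):
                stride = 2 if (si > 0 and b == 0) else 1
                mods.append(BasicBlock(in_ch, out_ch, rng, stride=stride))
                in_ch = out_ch
            stages.append(nn.Sequential(*mods))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages

    def forward(self, x: Tensor) -> EncoderPyramid:
        b, c, h, w = x.shape
        if c != 3:
            raise ValueError(f"expected a 3-channel image batch, got {c} channels")
        check_divisible(h, w)
        s2 = ag.relu(self.stem_bn(self.stem_conv(x)))
        h1 = ag.maxpool2d(s2, k=3, stride=2, pad=1)
        s4 = self.stage1(h1)
        s8 = self.stage2(s4)
        s16 = self.stage3(s8)
        s32 = self.stage4(s16)
        return EncoderPyramid(s2, s4, s8, s16, s32)


def build_encoder(
    pretrained: bool = False,
    seed: int = 0,
    width_scale: float = 1.0,
    weights_path: str | None = None,
) -> ResNetEncoder:
    """Construct the encoder with seeded He initialization.

    ``pretrained=True`` loads an ImageNet-initialized state dict from a local
    ``.npz`` file; no such file ships with the package, so a path must be
    supplied explicitly.
    """
    rng = np.random.default_rng(seed)
    enc = ResNetEncoder(rng, width_scale=width_scale)
    if pretrained:
        if weights_path is None:
            raise FileNotFoundError(
                "pretrained=True requires a local ImageNet weight file "
                "(pass weights_path=<encoder .npz state dict>); none is bundled"
            )
        with np.load(weights_path) as z:
            enc.load_state_dict(dict(z))
    return enc


def encode(encoder: ResNetEncoder, image_batch: np.ndarray | Tensor) -> EncoderPyramid:
    """Run the encoder on a (B, 3, H, W) batch; H and W must be /32."""
    x = image_batch if isinstance(image_batch, Tensor) else Tensor(np.asarray(image_batch))
    return encoder(x)
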