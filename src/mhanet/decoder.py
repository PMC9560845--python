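"""Multibranch hybrid attention (MHA) decoder and full-model assembly.

Each decoder stage receives the deep feature map and one encoder skip tap
and applies, in order: a channel-preserving stride-2 transposed convolution
(exact spatial doubling), concatenation with the (center-crop reconciled)
skip, two 3x3 conv+BN+ReLU layers — the first at the concatenated width,
the second reducing to the stage output width — SE channel attention, and
an elementwise summation with the skip. The output width of every stage
equals its skip width so the summation is well-typed.

Four such stages walk the encoder pyramid from stride 32 back to stride 2;
a fifth, skip-free transposed convolution reaches full resolution at
``head_channels`` (32 at full width), and two final 3x3 convolutions
produce the single-channel logit map. On an 800x800x3 input the recorded
intermediate sizes are 25x25x512 (bottleneck), 50x50x512 (upsampled),
50x50x768 (concat), 50x50x256 (stage-1 output), 100x100x384 (stage-2
concat), ..., 800x800x32 (pre-head).

The (use_psa, use_se, use_sum) flags reproduce the four ablation variants:
(F,F,F) baseline, (T,F,F) +PSA, (F,T,F) +SE, (T,T,T) full.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .encoder import EncoderPyramid, ResNetEncoder, check_divisible, scaled_widths
from .nn import autograd as ag
from .nn.autograd import Tensor
from .psa import PSABridge, PSAConfig


@dataclass(frozen=True)
class DecoderStageConfig:
    """One MHA decoder stage."""

    in_channels: int
    skip_channels: int
    out_channels: int
    upsample_kernel: int = 4
    use_se: bool = True
    use_sum: bool = True
    se_reduction: int = 16

    def __post_init__(self):
        if self.use_sum and self.out_channels != self.skip_channels:
            raise ValueError(
                f"use_sum requires out_channels == skip_channels, got "
                f"{self.out_channels} vs {self.skip_channels}"
            )

    @property
    def concat_channels(self) -> int:
        return self.in_channels + self.skip_channels


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture description; parameter count and every intermediate
    shape are derivable from it."""

    width_scale: float = 1.0
    use_psa: bool = True
    use_se: bool = True
    use_sum: bool = True
    head_channels: int | None = None  # default: 32 scaled by width_scale
    upsample_kernel: int = 4
    se_reduction: int = 16
    seed: int = 0
    psa: PSAConfig | None = None
    stages: tuple[DecoderStageConfig, ...] | None = None

    def resolve(self) -> "ModelConfig":
        """Fill derived fields (PSA geometry, stage chain, head width)."""
        ws = scaled_widths(self.width_scale)
        psa = self.psa
        if psa is None:
            psa = PSAConfig(se_reduction=self.se_reduction).scaled(self.width_scale)
        stages = self.stages
        if stages is None:
            skips = (ws[3], ws[2], ws[1], ws[0])  # stride 16, 8, 4, 2
            chain = (ws[4],) + skips[:-1]
            stages = tuple(
                DecoderStageConfig(
                    in_channels=c_in,
                    skip_channels=c_skip,
                    out_channels=c_skip,
                    upsample_kernel=self.upsample_kernel,
                    use_se=self.use_se,
                    use_sum=self.use_sum,
                    se_reduction=self.se_reduction,
                )
                for c_in, c_skip in zip(chain, skips)
            )
        head = self.head_channels
        if head is None:
            head = max(1, round(32 * self.width_scale))
        return replace(self, psa=psa, stages=stages, head_channels=head)

    def validate(self) -> "ModelConfig":
        cfg = self.resolve()
        ws = scaled_widths(cfg.width_scale)
        if cfg.use_psa and cfg.psa.in_channels != ws[4]:
            raise ValueError(
                f"PSA expects {cfg.psa.in_channels} channels but the bottleneck is {ws[4]}"
            )
        expect_in = ws[4]
        skips = (ws[3], ws[2], ws[1], ws[0])
        if len(cfg.stages) != 4:
            raise ValueError(f"expected 4 decoder stages, got {len(cfg.stages)}")
        for i, (st, skip) in enumerate(zip(cfg.stages, skips), start=1):
            if st.in_channels != expect_in:
                raise ValueError(
                    f"stage {i}: in_channels={st.in_channels} but the incoming "
                    f"feature has {expect_in} channels"
                )
            if st.skip_channels != skip:
                raise ValueError(
                    f"stage {i}: skip_channels={st.skip_channels} but the encoder "
                    f"tap has {skip} channels"
                )
            expect_in = st.out_channels
        return cfg

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        cfg = self.resolve()
        d = asdict(cfg)
        d["psa"] = asdict(cfg.psa)
        d["stages"] = [asdict(s) for s in cfg.stages]
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("psa") is not None:
            psa = dict(d["psa"])
            for k in ("kernel_sizes", "conv_groups"):
                psa[k] = tuple(psa[k])
            d["psa"] = PSAConfig(**psa)
        if d.get("stages") is not None:
            d["stages"] = tuple(DecoderStageConfig(**s) for s in d["stages"])
        return ModelConfig(**d)

    def ablation_label(self) -> str:
        flags = (self.use_psa, self.use_se, self.use_sum)
        return {
            (False, False, False): "baseline",
            (True, False, False): "baseline+PSA",
            (False, True, False): "baseline+SE",
            (True, True, True): "full",
        }.get(flags, f"psa={self.use_psa},se={self.use_se},sum={self.use_sum}")


def _center_crop(t: Tensor, h: int, w: int) -> Tensor:
    """Center-crop a (B,C,H,W) tensor by at most one pixel per edge."""
    _, _, th, tw = t.shape
    if (th, tw) == (h, w):
        return t
    if th < h or tw < w or th - h > 2 or tw - w > 2:
        raise ValueError(f"cannot reconcile feature sizes {th}x{tw} -> {h}x{w}")
    dh, dw = (th - h) // 2, (tw - w) // 2
    return t[:, :, dh : dh + h, dw : dw + w]


class MHAStage(nn.Module):
    """One decoder stage: upsample, concat, two 3x3 convs, SE, sum."""

    def __init__(self, cfg: DecoderStageConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.up = nn.ConvTranspose2d(
            cfg.in_channels, cfg.in_channels, rng, k=cfg.upsample_kernel, stride=2, pad=1
        )
        cw = cfg.concat_channels
        self.conv1 = nn.ConvBNReLU(cw, cw, 3, rng)
        self.conv2 = nn.ConvBNReLU(cw, cfg.out_channels, 3, rng)
        if cfg.use_se:
            self.se = nn.SEBlock(cfg.out_channels, rng, reduction=cfg.se_reduction)

    def forward(self, deep: Tensor, skip: Tensor, trace: list | None = None) -> Tensor:
        up = self.up(deep)
        _, _, sh, sw = skip.shape
        up = _center_crop(up, sh, sw)
        if trace is not None:
            trace.append(("upsampled", up.shape))
        h = ag.concat([up, skip], axis=1)
        if trace is not None:
            trace.append(("concat", h.shape))
        h = self.conv2(self.conv1(h))
        if self.cfg.use_se:
            h = self.se(h)
        if trace is not None:
            trace.append(("out", h.shape))
        if self.cfg.use_sum:
            h = ag.add(h, skip)
        return h


class MHANet(nn.Module):
    """Encoder -> (PSA bridge) -> four MHA stages -> full-resolution head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        cfg = config.validate()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = ResNetEncoder(rng, width_scale=cfg.width_scale)
        if cfg.use_psa:
            self.psa = PSABridge(cfg.psa, rng)
        for i, st in enumerate(cfg.stages, start=1):
            setattr(self, f"stage{i}", MHAStage(st, rng))
        last = cfg.stages[-1].out_channels
        self.final_up = nn.ConvTranspose2d(
            last, cfg.head_channels, rng, k=cfg.upsample_kernel, stride=2, pad=1
        )
        self.head1 = nn.ConvBNReLU(cfg.head_channels, cfg.head_channels, 3, rng)
        self.head2 = nn.Conv2d(cfg.head_channels, 1, 3, rng, pad=1, bias=True)

    def forward(self, x: Tensor, trace: list | None = None) -> Tensor:
        """Logit map (B, 1, H, W); apply a sigmoid for probabilities."""
        pyr: EncoderPyramid = self.encoder(x)
        h = pyr.bottleneck
        if trace is not None:
            trace.append(("bottleneck", h.shape))
        if self.config.use_psa:
            h = self.psa(h)
        skips = (pyr.tap_s16, pyr.tap_s8, pyr.tap_s4, pyr.tap_s2)
        for i, skip in enumerate(skips, start=1):
            stage: MHAStage = getattr(self, f"stage{i}")
            sub = [] if trace is not None else None
            h = stage(h, skip, trace=sub)
            if trace is not None:
                trace.extend((f"stage{i}.{lbl}", shp) for lbl, shp in sub)
        h = self.final_up(h)
        if trace is not None:
            trace.append(("prehead", h.shape))
        return self.head2(self.head1(h))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a (B, 3, H, W) float batch (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                logits = self.forward(Tensor(np.asarray(images, dtype=np.float32)))
            return ag._sigmoid(logits.numpy())
        finally:
            self.train(was_training)


def assemble_mhanet(config: ModelConfig) -> MHANet:
    """Build the full network from a validated :class:`ModelConfig`."""
    return MHANet(config)


def shape_trace(model: MHANet, input_hw: tuple[int, int]) -> dict[str, tuple[int, ...]]:
    """Record every intermediate feature-map shape on a zero input.

    Returns an ordered mapping label -> (B, C, H, W); on an 800x800 input
    of the full model this reproduces the printed architecture sizes
    (25x25x512 bottleneck through the 800x800x32 pre-head map).
    """
    h, w = input_hw
    check_divisible(h, w)
    x = Tensor(np.zeros((1, 3, h, w), dtype=np.float32))
    trace: list[tuple[str, tuple[int, ...]]] = []
    was_training = model.training
    model.eval()
    try:
        with ag.no_grad():
            out = model.forward(x, trace=trace)
    finally:
        model.train(was_training)
    trace.append(("output", out.shape))
    return dict(trace)


def ablation_configs(width_scale: float = 1.0, seed: int = 0) -> dict[str, ModelConfig]:
    """The four ablation variants: baseline, +PSA, +SE, full."""
    out = {}
    for use_psa, use_se, use_sum in [
        (False, False, False),
        (True, False, False),
        (False, True, False),
        (True, True, True),
    ]:
        cfg = ModelConfig(
            width_scale=width_scale,
            use_psa=use_psa,
            use_se=use_se,
            use_sum=use_sum,
            seed=seed,
        )
        out[cfg.ablation_label()] = cfg
    return out
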