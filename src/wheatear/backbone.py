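"""Asymmetric-bottleneck backbone with multi-scale P3/P4/P5 taps.

The backbone is a stack of 15 AsymmBottleneck (ASB) stages behind a
stride-2 stem.  An ASB stage is an inverted residual block in which part
of the pointwise expansion is replaced by the input channels themselves:
the 1x1 expansion only produces ``exp_size - in_channels`` new channels
and the input is concatenated alongside them, saving parameters while
keeping the depthwise convolution's working width at ``exp_size``.

Layout of one stage (TanhExp after the expansion and depthwise stages,
linear after the projection, residual add when stride 1 and matching
channels)::

    x -(1x1 conv, BN, TanhExp)-> new     # exp_size - C_in channels
    concat(x, new)                       # exp_size channels
      -(kxk depthwise, BN, TanhExp)
      -(SPSA, on marked stages)
      -(1x1 conv, BN)-> out              # linear bottleneck
    + x  (if stride == 1 and C_in == C_out)

Three stage outputs are tapped as the feature pyramid: P3 at stride 8,
P4 at stride 16 and P5 at stride 32 relative to the input image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .activations import TanhExp
from .attention import SPSA, SPSAConfig
from .nn import BatchNorm2d, Conv2d, Module


@dataclass(frozen=True)
class ASBConfig:
    """One row of the backbone table."""

    kernel: int
    exp_size: int
    out_channels: int
    use_spsa: bool
    stride: int

    def __post_init__(self):
        if self.kernel not in (3, 5):
            raise ValueError(f"kernel must be 3 or 5, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.out_channels < 1 or self.exp_size < self.out_channels:
            raise ValueError("exp_size must be >= out_channels >= 1")


@dataclass(frozen=True)
class BackboneSpec:
    """Ordered stage list plus the pyramid tap indices (0-based)."""

    stages: tuple[ASBConfig, ...]
    taps: tuple[int, int, int]
    stem_channels: int = 16
    spsa: SPSAConfig = field(default_factory=SPSAConfig)

    def __post_init__(self):
        if len(self.taps) != 3 or list(self.taps) != sorted(set(self.taps)):
            raise ValueError("taps must be 3 strictly increasing indices")
        if max(self.taps) >= len(self.stages):
            raise ValueError("tap index beyond last stage")

    def channel_trace(self) -> list[int]:
        """Input channel count seen by each stage, starting at the stem."""
        trace = [self.stem_channels]
        for cfg in self.stages[:-1]:
            trace.append(cfg.out_channels)
        return trace

    def stride_trace(self) -> list[int]:
        """Cumulative stride after each stage (stem contributes 2)."""
        s, out = 2, []
        for cfg in self.stages:
            s *= cfg.stride
            out.append(s)
        return out


# The 15-stage table: (kernel, exp_size, out_channels, use_spsa, stride).
# SPSA rides on the three 40-channel, the two 112-channel and the three
# final 160-channel stages.  Taps: P3 after stage 6, P4 after stage 12,
# P5 after stage 15 (1-based).
_DEFAULT_ROWS = (
    (3, 16, 16, False, 1),
    (3, 64, 24, False, 2),
    (3, 72, 24, False, 1),
    (5, 72, 40, True, 2),
    (5, 120, 40, True, 1),
    (5, 120, 40, True, 1),    # P3 tap, stride 8
    (3, 240, 80, False, 2),
    (3, 200, 80, False, 1),
    (3, 184, 80, False, 1),
    (3, 184, 80, False, 1),
    (3, 480, 112, True, 1),
    (3, 672, 112, True, 1),   # P4 tap, stride 16
    (5, 672, 160, True, 2),
    (5, 960, 160, True, 1),
    (5, 960, 160, True, 1),   # P5 tap, stride 32
)


def default_backbone_spec() -> BackboneSpec:
    """The full-width 15-stage backbone specification."""
    stages = tuple(ASBConfig(*row) for row in _DEFAULT_ROWS)
    return BackboneSpec(stages=stages, taps=(5, 11, 14))


def _round_channels(c: int, width: float, divisor: int) -> int:
    return max(divisor, int(round(c * width / divisor)) * divisor)


def scaled_backbone_spec(width_multiple: float, divisor: int = 8) -> BackboneSpec:
    """A width-scaled variant for CPU-scale training experiments.

    Channel counts are multiplied by ``width_multiple`` and rounded to a
    multiple of ``divisor`` (8 keeps every SPSA group/halving valid).
    """
    base = default_backbone_spec()
    stages = []
    for cfg in base.stages:
        out = _round_channels(cfg.out_channels, width_multiple, divisor)
        exp = max(out, _round_channels(cfg.exp_size, width_multiple, divisor))
        stages.append(replace(cfg, exp_size=exp, out_channels=out))
    stem = _round_channels(base.stem_channels, width_multiple, divisor)
    return BackboneSpec(stages=tuple(stages), taps=base.taps,
                        stem_channels=stem, spsa=base.spsa)


class ASBBlock(Module):
    """One AsymmBottleneck stage (see module docstring for the layout)."""

    def __init__(self, in_channels: int, cfg: ASBConfig,
                 spsa_cfg: SPSAConfig = SPSAConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cfg.exp_size < in_channels:
            raise ValueError(
                f"exp_size={cfg.exp_size} smaller than input width "
                f"{in_channels}: nothing left for the carried identity")
        self.cfg = cfg
        self.in_channels = in_channels
        self.expand_channels = cfg.exp_size - in_channels
        self.use_residual = cfg.stride == 1 and in_channels == cfg.out_channels
        if self.expand_channels > 0:
            self.expand = Conv2d(in_channels, self.expand_channels, 1,
                                 bias=False, rng=rng)
            self.expand_bn = BatchNorm2d(self.expand_channels)
        else:
            self.expand = None
        self.act = TanhExp()
        self.dw = Conv2d(cfg.exp_size, cfg.exp_size, cfg.kernel,
                         stride=cfg.stride, groups=cfg.exp_size,
                         bias=False, rng=rng)
        self.dw_bn = BatchNorm2d(cfg.exp_size)
        self.spsa = SPSA(cfg.exp_size, spsa_cfg, rng) if cfg.use_spsa else None
        self.project = Conv2d(cfg.exp_size, cfg.out_channels, 1,
                              bias=False, rng=rng)
        self.project_bn = BatchNorm2d(cfg.out_channels)

    def forward(self, x):
        from . import autodiff as ad
        if self.expand is not None:
            new = self.act(self.expand_bn(self.expand(x)))
            h = ad.concat([x, new], axis=1)
        else:
            h = x
        h = self.act(self.dw_bn(self.dw(h)))
        if self.spsa is not None:
            h = self.spsa(h)
        h = self.project_bn(self.project(h))
        if self.use_residual:
            h = h + x
        return h

    def parameter_count(self) -> int:
        """Closed-form weight count (convolutions + BN affine + SPSA)."""
        return sum(p.size for p in self.parameters())


class MultiScaleFeatures(NamedTuple):
    """P3/P4/P5 feature maps at strides 8/16/32."""

    p3: object
    p4: object
    p5: object


class Backbone(Module):
    """Stem + 15 ASB stages, returning the tapped pyramid levels."""

    def __init__(self, spec: BackboneSpec | None = None, seed: int = 0):
        super().__init__()
        self.spec = spec or default_backbone_spec()
        rng = np.random.default_rng(seed)
        self.stem = Conv2d(3, self.spec.stem_channels, 3, stride=2,
                           bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(self.spec.stem_channels)
        self.act = TanhExp()
        self.blocks = []
        in_ch = self.spec.stem_channels
        for i, cfg in enumerate(self.spec.stages):
            blk = ASBBlock(in_ch, cfg, self.spec.spsa, rng)
            setattr(self, f"stage{i}", blk)
            self.blocks.append(blk)
            in_ch = cfg.out_channels

    @property
    def out_channels(self) -> tuple[int, int, int]:
        return tuple(self.spec.stages[t].out_channels for t in self.spec.taps)

    def forward(self, x) -> MultiScaleFeatures:
        h_img, w_img = x.shape[2], x.shape[3]
        if h_img % 32 or w_img % 32:
            raise ValueError(
                f"input spatial size {h_img}x{w_img} must be divisible by 32")
        h = self.act(self.stem_bn(self.stem(x)))
        taps = []
        tapset = set(self.spec.taps)
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if i in tapset:
                taps.append(h)
        return MultiScaleFeatures(*taps)
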