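"""Shuffle Polarized Self-Attention (SPSA).

The block splits the channel axis into G groups; inside each group half the
channels go through a *channel-only* polarized attention branch and the
other half through a *spatial-only* branch.  "Polarized" means one axis is
fully collapsed (to 1 channel, or to a single spatial vector via global
pooling) while the other keeps full resolution; a softmax restores dynamic
range and a logistic gate produces multiplicative weights in (0, 1).
Group outputs are concatenated and a channel shuffle moves information
across groups.

Both branches are zero-preserving when built bias-free: an all-zero input
yields an all-zero output (the gate is 0.5 but multiplies zeros).

The channel branch, for a slice with c channels (internal width ci = c/2
by default):

    V = reshape(W_v x)            # (ci, H*W)  value pathway
    q = softmax(flatten(W_q x))   # (H*W,)     one-channel query over space
    A = sigmoid(W_z (V q))        # (c, 1, 1)  per-channel gate
    Z = A * x                     # broadcast over each channel plane

The spatial branch:

    q = softmax(GAP(W_q x))       # (ci,)      channel query from pooling
    V = reshape(W_v x)            # (ci, H*W)
    A = sigmoid(reshape(q V))     # (1, H, W)  per-position gate
    Z = A * x                     # broadcast over channels
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .nn import Conv2d, Module


@dataclass(frozen=True)
class SPSAConfig:
    """Grouping and internal-width settings for an SPSA block.

    groups: number of channel groups G (G must divide C, and each group
        must split into two even halves).
    internal_ratio: fraction of a branch's channels used inside the
        polarized projections (the "compress" width).
    """

    groups: int = 2
    internal_ratio: float = 0.5

    def validate(self, channels: int) -> None:
        if self.groups < 1 or channels % self.groups:
            raise ValueError(
                f"groups={self.groups} must divide channels={channels}")
        per_group = channels // self.groups
        if per_group % 2:
            raise ValueError(
                f"per-group channel count {per_group} must be even "
                "(each group splits into a channel and a spatial half)")
        half = per_group // 2
        ci = half * self.internal_ratio
        if ci < 1 or abs(ci - round(ci)) > 1e-9:
            raise ValueError(
                f"internal_ratio={self.internal_ratio} does not give an "
                f"integer internal width >= 1 for branch channels {half}")


def channel_shuffle(x, groups: int):
    """Permute channels by the (G, C/G) transpose; pure reordering.

    Works on both plain ndarrays and autodiff tensors.
    """
    n, c = x.shape[0], x.shape[1]
    if c % groups:
        raise ValueError(f"groups={groups} must divide channels={c}")
    rest = x.shape[2:]
    if isinstance(x, ad.Tensor):
        y = ad.reshape(x, (n, groups, c // groups) + tuple(rest))
        y = ad.transpose(y, (0, 2, 1) + tuple(range(3, 3 + len(rest))))
        return ad.reshape(y, (n, c) + tuple(rest))
    y = x.reshape((n, groups, c // groups) + tuple(rest))
    y = y.swapaxes(1, 2)
    return y.reshape((n, c) + tuple(rest))


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The channel index permutation channel_shuffle applies."""
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


class ChannelBranch(Module):
    """Channel-only polarized attention on a c-channel slice."""

    def __init__(self, channels: int, internal_ratio: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels < 2:
            raise ValueError("channel branch needs at least 2 channels")
        ci = channels * internal_ratio
        if ci < 1 or abs(ci - round(ci)) > 1e-9:
            raise ValueError(
                f"channels={channels} with internal_ratio={internal_ratio} "
                "gives a non-integer internal width")
        self.channels = channels
        self.internal = int(round(ci))
        self.wv = Conv2d(channels, self.internal, 1, bias=False, rng=rng)
        self.wq = Conv2d(channels, 1, 1, bias=False, rng=rng)
        self.wz = Conv2d(self.internal, channels, 1, bias=False, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        v = ad.reshape(self.wv(x), (n, self.internal, h * w))
        q = ad.softmax(ad.reshape(self.wq(x), (n, h * w, 1)), axis=1)
        a = ad.matmul(v, q)                      # (n, ci, 1)
        a = ad.reshape(a, (n, self.internal, 1, 1))
        gate = ad.sigmoid(self.wz(a))            # (n, c, 1, 1)
        return x * gate


class SpatialBranch(Module):
    """Spatial-only polarized attention on a c-channel slice."""

    def __init__(self, channels: int, internal_ratio: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels < 2:
            raise ValueError("spatial branch needs at least 2 channels")
        ci = channels * internal_ratio
        if ci < 1 or abs(ci - round(ci)) > 1e-9:
            raise ValueError(
                f"channels={channels} with internal_ratio={internal_ratio} "
                "gives a non-integer internal width")
        self.channels = channels
        self.internal = int(round(ci))
        self.wq = Conv2d(channels, self.internal, 1, bias=False, rng=rng)
        self.wv = Conv2d(channels, self.internal, 1, bias=False, rng=rng)

    def forward(self, x):
        n, c, h, w = x.shape
        q = self.wq(x).mean(axis=(2, 3))          # (n, ci) global pooling
        q = ad.softmax(q, axis=1)
        q = ad.reshape(q, (n, 1, self.internal))
        v = ad.reshape(self.wv(x), (n, self.internal, h * w))
        amap = ad.reshape(ad.matmul(q, v), (n, 1, h, w))
        return x * ad.sigmoid(amap)


class SPSA(Module):
    """The full shuffle polarized self-attention block.

    Shape-preserving multiplicative reweighting of an (N, C, H, W) map.
    """

    def __init__(self, channels: int, cfg: SPSAConfig = SPSAConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate(channels)
        self.channels = channels
        self.cfg = cfg
        per_group = channels // cfg.groups
        self.half = per_group // 2
        for g in range(cfg.groups):
            setattr(self, f"ch{g}",
                    ChannelBranch(self.half, cfg.internal_ratio, rng))
            setattr(self, f"sp{g}",
                    SpatialBranch(self.half, cfg.internal_ratio, rng))

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        per_group = 2 * self.half
        outs = []
        for g in range(self.cfg.groups):
            lo = g * per_group
            xa = x[:, lo:lo + self.half]
            xb = x[:, lo + self.half:lo + per_group]
            outs.append(getattr(self, f"ch{g}")(xa))
            outs.append(getattr(self, f"sp{g}")(xb))
        y = ad.concat(outs, axis=1)
        return channel_shuffle(y, self.cfg.groups)
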