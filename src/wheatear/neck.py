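"""PANet-style neck, YOLO heads, anchor handling and box decoding.

The neck runs a top-down pass (upsample the deeper level, concatenate with
the shallower, fuse with a 1x1 convolution) followed by a bottom-up pass
(stride-2 3x3 convolution down, concatenate, fuse), one fusion per
junction.  Three 1x1 heads then emit, per anchor and grid cell, the raw
vector (tx, ty, tw, th, objectness, class logit) for the single
wheat-ear class.

Decoding follows the standard anchor-based grid parameterisation:

    cx = (sigmoid(tx) + j) * stride       w = anchor_w * exp(tw)
    cy = (sigmoid(ty) + i) * stride       h = anchor_h * exp(th)

with confidence sigmoid(obj) * sigmoid(cls), boxes clipped to the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .activations import TanhExp
from .backbone import Backbone, BackboneSpec, MultiScaleFeatures, \
    default_backbone_spec, scaled_backbone_spec
from .boxes import Box
from .nn import BatchNorm2d, Conv2d, Module

STRIDES = (8, 16, 32)
ANCHORS_PER_LEVEL = 3


@dataclass(frozen=True)
class NeckConfig:
    """Per-level channel widths after each fusion (P3, P4, P5 order)."""

    widths: tuple[int, int, int] = (40, 112, 160)

    def __post_init__(self):
        if len(self.widths) != 3 or any(w < 1 for w in self.widths):
            raise ValueError("widths must be 3 positive integers")


class AnchorSet:
    """Nine (w, h) prior sizes in input pixels, three per pyramid level.

    Anchors are stored sorted by area; the smallest triple serves P3 and
    the largest serves P5.
    """

    def __init__(self, sizes):
        arr = np.asarray(sizes, dtype=np.float64).reshape(-1, 2)
        if arr.shape[0] != 9:
            raise ValueError("an AnchorSet holds exactly 9 (w, h) pairs")
        if np.any(arr <= 0):
            raise ValueError("anchor sizes must be positive")
        order = np.argsort(arr[:, 0] * arr[:, 1], kind="stable")
        self.sizes = arr[order]

    def level(self, idx: int) -> np.ndarray:
        """The (3, 2) anchor slice for pyramid level idx (0 = P3)."""
        return self.sizes[idx * 3:(idx + 1) * 3]

    def tolist(self):
        return [[float(w), float(h)] for w, h in self.sizes]

    def __eq__(self, other):
        return isinstance(other, AnchorSet) and np.allclose(self.sizes, other.sizes)


def default_anchors() -> AnchorSet:
    """Fallback priors: compact square-ish sizes spanning 16-256 px."""
    return AnchorSet([(16, 16), (24, 32), (40, 28),
                      (48, 48), (64, 80), (96, 72),
                      (128, 128), (176, 224), (256, 256)])


def _wh_iou(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """IoU of centred boxes given only widths/heights; (N, K) matrix."""
    inter = (np.minimum(wh[:, None, 0], anchors[None, :, 0])
             * np.minimum(wh[:, None, 1], anchors[None, :, 1]))
    union = wh[:, 0:1] * wh[:, 1:2] + (anchors[:, 0] * anchors[:, 1])[None] - inter
    return inter / union


def fit_anchors(wh, k: int = 9, seed: int = 0, iters: int = 100) -> AnchorSet:
    """K-means over box sizes under the 1 - IoU distance.

    Initialised deterministically at area quantiles, refined by Lloyd
    iterations; ``seed`` only matters for the (rare) re-draw of emptied
    clusters.  With fewer boxes than k this raises.
    """
    wh = np.asarray(wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(wh)}")
    rng = np.random.default_rng(seed)
    order = np.argsort(wh[:, 0] * wh[:, 1], kind="stable")
    centers = wh[order[np.linspace(0, len(wh) - 1, k).round().astype(int)]].copy()
    assign = None
    for _ in range(iters):
        d = 1.0 - _wh_iou(wh, centers)
        new_assign = d.argmin(axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                centers[j] = wh[rng.integers(len(wh))]
    if k == 9:
        return AnchorSet(centers)
    order = np.argsort(centers[:, 0] * centers[:, 1], kind="stable")
    return centers[order]


class ConvBNAct(Module):
    def __init__(self, cin, cout, k, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = TanhExp()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Neck(Module):
    """Top-down + bottom-up path aggregation over P3/P4/P5."""

    def __init__(self, in_channels: tuple[int, int, int],
                 cfg: NeckConfig = NeckConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        c3, c4, c5 = in_channels
        w3, w4, w5 = cfg.widths
        # top-down: deeper level is upsampled and fused into the shallower
        self.lat5 = ConvBNAct(c5, w5, 1, rng=rng)
        self.fuse4 = ConvBNAct(c4 + w5, w4, 1, rng=rng)
        self.fuse3 = ConvBNAct(c3 + w4, w3, 1, rng=rng)
        # bottom-up: stride-2 conv down, concatenate, fuse
        self.down3 = ConvBNAct(w3, w3, 3, stride=2, rng=rng)
        self.fuse4b = ConvBNAct(w4 + w3, w4, 1, rng=rng)
        self.down4 = ConvBNAct(w4, w4, 3, stride=2, rng=rng)
        self.fuse5b = ConvBNAct(w5 + w4, w5, 1, rng=rng)

    def forward(self, feats: MultiScaleFeatures) -> MultiScaleFeatures:
        p3, p4, p5 = feats
        if not (p3.shape[2] == 2 * p4.shape[2] == 4 * p5.shape[2]
                and p3.shape[3] == 2 * p4.shape[3] == 4 * p5.shape[3]):
            raise ValueError("pyramid levels must halve in spatial size")
        t5 = self.lat5(p5)
        t4 = self.fuse4(ad.concat([p4, ad.upsample_nearest2x(t5)], axis=1))
        t3 = self.fuse3(ad.concat([p3, ad.upsample_nearest2x(t4)], axis=1))
        n4 = self.fuse4b(ad.concat([t4, self.down3(t3)], axis=1))
        n5 = self.fuse5b(ad.concat([t5, self.down4(n4)], axis=1))
        return MultiScaleFeatures(t3, n4, n5)


class DetectionHead(Module):
    """One 1x1 convolution per level to 3 x (4 box + 1 obj + 1 class)."""

    VEC = 6

    def __init__(self, in_channels: tuple[int, int, int],
                 rng: np.random.Generator | None = None,
                 obj_bias: float = -4.0):
        super().__init__()
        for i, c in enumerate(in_channels):
            conv = Conv2d(c, ANCHORS_PER_LEVEL * self.VEC, 1, bias=True, rng=rng)
            # start objectness strongly negative: a fresh model should be
            # near-silent rather than flooding NMS with half-confident boxes
            b = conv.bias.data.reshape(ANCHORS_PER_LEVEL, self.VEC)
            b[:, 4] = obj_bias
            conv.bias.data = b.reshape(-1)
            setattr(self, f"head{i}", conv)

    def forward(self, feats: MultiScaleFeatures):
        out = []
        for i, f in enumerate(feats):
            n, _, h, w = f.shape
            raw = getattr(self, f"head{i}")(f)
            raw = ad.reshape(raw, (n, ANCHORS_PER_LEVEL, self.VEC, h, w))
            out.append(ad.transpose(raw, (0, 1, 3, 4, 2)))  # (N, A, H, W, 6)
        return out


def decode(predictions, anchors: AnchorSet, conf_threshold: float,
           image_size: tuple[int, int]) -> list[list[Box]]:
    """Raw grids -> pixel-space boxes per batch element.

    ``predictions`` is the head output: one (N, 3, H, W, 6) array per
    level.  Returns one Box list per image, unsorted, NMS not applied.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must be in [0, 1]")
    img_w, img_h = image_size
    arrays = [p.data if isinstance(p, ad.Tensor) else np.asarray(p)
              for p in predictions]
    n_batch = arrays[0].shape[0]
    results: list[list[Box]] = [[] for _ in range(n_batch)]
    for lvl, raw in enumerate(arrays):
        stride = STRIDES[lvl]
        n, a, h, w, _ = raw.shape
        sig = 1.0 / (1.0 + np.exp(-raw[..., :2]))
        jj = np.arange(w).reshape(1, 1, 1, w)
        ii = np.arange(h).reshape(1, 1, h, 1)
        cx = (sig[..., 0] + jj) * stride
        cy = (sig[..., 1] + ii) * stride
        lvl_anchors = anchors.level(lvl)
        aw = lvl_anchors[:, 0].reshape(1, a, 1, 1)
        ah = lvl_anchors[:, 1].reshape(1, a, 1, 1)
        bw = aw * np.exp(np.minimum(raw[..., 2], 8.0))
        bh = ah * np.exp(np.minimum(raw[..., 3], 8.0))
        obj = 1.0 / (1.0 + np.exp(-raw[..., 4]))
        cls = 1.0 / (1.0 + np.exp(-raw[..., 5]))
        conf = obj * cls
        keep = conf >= conf_threshold
        for b in range(n):
            m = keep[b]
            if not m.any():
                continue
            x1 = np.clip(cx[b][m] - bw[b][m] / 2, 0, img_w)
            y1 = np.clip(cy[b][m] - bh[b][m] / 2, 0, img_h)
            x2 = np.clip(cx[b][m] + bw[b][m] / 2, 0, img_w)
            y2 = np.clip(cy[b][m] + bh[b][m] / 2, 0, img_h)
            cf = conf[b][m]
            good = (x2 > x1) & (y2 > y1)
            results[b].extend(
                Box(float(a_), float(b_), float(c_), float(d_),
                    confidence=float(e_), class_id=0)
                for a_, b_, c_, d_, e_
                in zip(x1[good], y1[good], x2[good], y2[good], cf[good]))
    return results


def encode_box(box, anchor_wh, cell_ij, stride: int) -> tuple[float, float, float, float]:
    """Inverse of the decode parameterisation for one positive target.

    Returns (tx, ty, tw, th) such that decoding them at grid cell
    ``cell_ij = (i, j)`` with the given anchor reproduces the box.  The
    centre must lie strictly inside the cell (sigmoid is invertible only
    on the open interval).
    """
    x1, y1, x2, y2 = box.x1, box.y1, box.x2, box.y2
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    i, j = cell_ij
    fx = cx / stride - j
    fy = cy / stride - i
    if not (0 < fx < 1 and 0 < fy < 1):
        raise ValueError("box centre does not fall inside the given cell")
    logit = lambda p: float(np.log(p / (1 - p)))
    tw = float(np.log((x2 - x1) / anchor_wh[0]))
    th = float(np.log((y2 - y1) / anchor_wh[1]))
    return logit(fx), logit(fy), tw, th


class Detector(Module):
    """Backbone + neck + heads: the complete single-stage wheat-ear model."""

    def __init__(self, spec: BackboneSpec | None = None,
                 neck_cfg: NeckConfig | None = None,
                 anchors: AnchorSet | None = None,
                 width_multiple: float = 1.0,
                 seed: int = 0):
        super().__init__()
        if spec is None:
            spec = (default_backbone_spec() if width_multiple == 1.0
                    else scaled_backbone_spec(width_multiple))
        self.backbone = Backbone(spec, seed=seed)
        bb_out = self.backbone.out_channels
        if neck_cfg is None:
            neck_cfg = NeckConfig(widths=bb_out)
        rng = np.random.default_rng(seed + 1)
        self.neck = Neck(bb_out, neck_cfg, rng=rng)
        self.head = DetectionHead(neck_cfg.widths, rng=rng)
        self.anchors = anchors or default_anchors()

    def forward(self, x):
        return self.head(self.neck(self.backbone(x)))

    def predict(self, images: np.ndarray, conf_threshold: float = 0.25,
                nms_threshold: float = 0.45) -> list[list[Box]]:
        """Float images (N, 3, H, W) in [0, 1] -> final boxes per image."""
        from .evaluation import nms
        self.eval()
        with ad.no_grad():
            preds = self.forward(ad.Tensor(np.asarray(images, dtype=np.float32)))
        img_size = (images.shape[3], images.shape[2])
        decoded = decode(preds, self.anchors, conf_threshold, img_size)
        return [nms(b, nms_threshold) for b in decoded]
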