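"""Synthetic wheat-field scenes with exact ground truth.

The generator emulates the *geometric and statistical* properties of field
imagery of wheat at heading stage — dense, overlapping, elongated ear-like
objects (20-70 per full-size image) at mixed orientations over a
green-brown textured background — without attempting photorealism.  Ears
are rendered as oriented, textured ellipses with short awn strokes; the
recorded bounding box is the tight axis-aligned box of the actually
rendered pixels, so labels and geometry agree exactly.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .boxes import Box


@dataclass(frozen=True)
class SynthConfig:
    """Scene statistics; defaults follow the emulated field imagery.

    ``ear_count_range`` is inclusive.  Ear axis lengths are fractions of
    the image size so that configurations scale with resolution.
    ``overlap`` > 0 lets ears cluster (centres drawn around a few clump
    centres); ``background_similarity`` in [0, 1] pulls the background
    palette toward the ear palette, making scenes harder.
    """

    image_size: int = 1024
    ear_count_range: tuple[int, int] = (20, 70)
    ear_length_frac: tuple[float, float] = (0.05, 0.11)
    ear_aspect: tuple[float, float] = (2.2, 3.6)
    orientation_deg: tuple[float, float] = (-90.0, 90.0)
    overlap: float = 0.5
    background_similarity: float = 0.35
    color_jitter: float = 0.15

    def __post_init__(self):
        for lo, hi in (self.ear_count_range, self.ear_length_frac,
                       self.ear_aspect, self.orientation_deg):
            if lo > hi:
                raise ValueError("range minimum exceeds maximum")
        if self.ear_count_range[0] < 1:
            raise ValueError("need at least one ear per scene")


def easy_config(image_size: int = 256) -> SynthConfig:
    """A deliberately separable variant for training-recovery checks:
    fewer, larger, mostly isolated ears on a dissimilar background."""
    return SynthConfig(image_size=image_size,
                       ear_count_range=(3, 8),
                       ear_length_frac=(0.18, 0.30),
                       ear_aspect=(2.0, 3.0),
                       orientation_deg=(-35.0, 35.0),
                       overlap=0.0,
                       background_similarity=0.0,
                       color_jitter=0.08)


@dataclass
class Scene:
    image: np.ndarray          # (H, W, 3) uint8
    boxes: list[Box]
    seed: int


def _noise_texture(rng, size, scale, lo, hi):
    """Smooth scalar noise field in [lo, hi]."""
    coarse = rng.random((max(2, size // scale),) * 2)
    field = ndimage.zoom(coarse, size / coarse.shape[0], order=1)[:size, :size]
    field = (field - field.min()) / max(np.ptp(field), 1e-9)
    return lo + field * (hi - lo)


def _background(rng, cfg: SynthConfig) -> np.ndarray:
    s = cfg.image_size
    # green-brown canopy: hue field blending leaf green and soil brown
    mix = _noise_texture(rng, s, 16, 0.0, 1.0)
    green = np.array([70, 105, 45], dtype=np.float64)
    brown = np.array([95, 80, 55], dtype=np.float64)
    img = mix[..., None] * green + (1 - mix[..., None]) * brown
    img += rng.normal(0, 12, size=(s, s, 3))
    if cfg.background_similarity > 0:
        ear_tone = np.array([188, 168, 96], dtype=np.float64)
        img = (1 - cfg.background_similarity) * img \
            + cfg.background_similarity * ear_tone
    return np.clip(img, 0, 255)


def _render_ear(img, rng, cfg, cx, cy, half_len, half_wid, theta):
    """Draw one textured ellipse + awns; return its tight pixel box."""
    s = cfg.image_size
    margin = int(math.ceil(half_len)) + 3
    x0, x1 = max(0, int(cx) - margin), min(s, int(cx) + margin + 1)
    y0, y1 = max(0, int(cy) - margin), min(s, int(cy) + margin + 1)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx + 0.5) - cx
    dy = (yy + 0.5) - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st          # along the ear axis
    w = -dx * st + dy * ct         # across
    mask = (u / half_len) ** 2 + (w / half_wid) ** 2 <= 1.0
    if not mask.any():
        return None
    # spikelet-like texture: bands along the axis plus speckle
    base = np.array([185 + rng.normal(0, 10), 165 + rng.normal(0, 10),
                     90 + rng.normal(0, 8)])
    base *= 1.0 + rng.uniform(-cfg.color_jitter, cfg.color_jitter)
    bands = 0.82 + 0.18 * np.cos(u / max(half_wid * 0.8, 1.0) * math.pi)
    speckle = rng.normal(1.0, 0.05, size=mask.shape)
    shade = np.clip(bands * speckle, 0.55, 1.25)
    patch = img[y0:y1, x0:x1]
    patch[mask] = np.clip(base[None, :] * shade[mask, None], 0, 255)
    # a few awn strokes poking out of the tip (part of the labelled ear)
    tipx, tipy = cx + half_len * ct, cy + half_len * st
    awn_x, awn_y = [], []
    for _ in range(rng.integers(2, 5)):
        ang = theta + rng.normal(0, 0.25)
        length = half_len * rng.uniform(0.25, 0.5)
        n_pts = max(int(length * 2), 2)
        t = np.linspace(0, 1, n_pts)
        ax = (tipx + t * length * math.cos(ang)).astype(int)
        ay = (tipy + t * length * math.sin(ang)).astype(int)
        ok = (ax >= 0) & (ax < s) & (ay >= 0) & (ay < s)
        img[ay[ok], ax[ok]] = np.clip(base * 0.9, 0, 255)
        awn_x.append(ax[ok])
        awn_y.append(ay[ok])
    # tight box of everything rendered: ellipse body plus awns
    ys, xs = np.nonzero(mask)
    xs = np.concatenate([x0 + xs] + awn_x)
    ys = np.concatenate([y0 + ys] + awn_y)
    bx1, bx2 = xs.min(), xs.max() + 1
    by1, by2 = ys.min(), ys.max() + 1
    if bx2 - bx1 < 2 or by2 - by1 < 2:
        return None
    return Box(float(bx1), float(by1), float(bx2), float(by2))


def sample_scene(cfg: SynthConfig = SynthConfig(), seed: int = 0) -> Scene:
    """Render one scene; deterministic in (cfg, seed)."""
    rng = np.random.default_rng(seed)
    s = cfg.image_size
    img = _background(rng, cfg)
    n_target = int(rng.integers(cfg.ear_count_range[0],
                                cfg.ear_count_range[1] + 1))
    # clump centres emulate row planting / patchiness when overlap > 0
    if cfg.overlap > 0:
        n_clumps = max(1, n_target // 8)
        clumps = rng.uniform(0.15 * s, 0.85 * s, size=(n_clumps, 2))
    boxes: list[Box] = []
    attempts = 0
    while len(boxes) < n_target and attempts < n_target * 30:
        attempts += 1
        half_len = 0.5 * s * rng.uniform(*cfg.ear_length_frac)
        aspect = rng.uniform(*cfg.ear_aspect)
        half_wid = max(half_len / aspect, 1.5)
        theta = math.radians(rng.uniform(*cfg.orientation_deg))
        margin = half_len + 2
        if margin * 2 + 4 >= s:
            continue
        if cfg.overlap > 0 and rng.random() < 0.7:
            cx, cy = clumps[rng.integers(len(clumps))] \
                + rng.normal(0, 0.08 * s, size=2)
        else:
            cx = rng.uniform(margin, s - margin)
            cy = rng.uniform(margin, s - margin)
        if not (margin <= cx <= s - margin and margin <= cy <= s - margin):
            continue
        box = _render_ear(img, rng, cfg, cx, cy, half_len, half_wid, theta)
        if box is None:
            continue
        if cfg.overlap == 0.0:
            # easy mode keeps ears separated
            too_close = any(
                _box_iou(box, b) > 0.05 for b in boxes)
            if too_close:
                continue
        boxes.append(box)
    return Scene(image=img.astype(np.uint8), boxes=boxes, seed=seed)


def _box_iou(a: Box, b: Box) -> float:
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    return inter / (a.area + b.area - inter)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_KNOWN_OPS = ("scale", "mirror", "rotate", "saturation")


def augment(scene: Scene, ops, seed: int = 0,
            min_box_area: float = 4.0) -> Scene:
    """Apply the training-time augmentations with box remapping.

    ops is an ordered subset of {scale, mirror, rotate, saturation}.
    ``scale`` resizes by a factor in [0.7, 1.3], ``rotate`` spins within
    +-15 degrees about the image centre (boxes become the tight hull of
    their rotated corners, clipped), ``saturation`` rescales colourfulness
    only.  Boxes whose clipped area falls below ``min_box_area`` drop out.
    """
    rng = np.random.default_rng(seed)
    img = scene.image.astype(np.float64)
    boxes = [Box(b.x1, b.y1, b.x2, b.y2) for b in scene.boxes]
    for op in ops:
        if op not in _KNOWN_OPS:
            raise ValueError(f"unknown augmentation op {op!r}")
        if op == "mirror":
            img = img[:, ::-1].copy()
            w_img = img.shape[1]
            boxes = [Box(w_img - b.x2, b.y1, w_img - b.x1, b.y2)
                     for b in boxes]
        elif op == "scale":
            factor = rng.uniform(0.7, 1.3)
            img, boxes = scale_scene(img, boxes, factor)
        elif op == "rotate":
            angle = rng.uniform(-15.0, 15.0)
            img, boxes = rotate_scene(img, boxes, angle,
                                      min_box_area=min_box_area)
        elif op == "saturation":
            factor = rng.uniform(0.6, 1.4)
            mean = img.mean(axis=2, keepdims=True)
            img = np.clip(mean + factor * (img - mean), 0, 255)
    return Scene(image=np.clip(img, 0, 255).astype(np.uint8),
                 boxes=boxes, seed=scene.seed)


def scale_scene(img, boxes, factor: float):
    """Resize image by ``factor``; box coordinates multiply by it."""
    zoomed = ndimage.zoom(img, (factor, factor, 1.0), order=1)
    boxes = [Box(b.x1 * factor, b.y1 * factor, b.x2 * factor, b.y2 * factor)
             for b in boxes]
    return zoomed, boxes


def rotate_scene(img, boxes, angle_deg: float, min_box_area: float = 4.0):
    """Rotate about the image centre, keeping the canvas size.

    Each box is replaced by the tight axis-aligned hull of its rotated
    corners, clipped to the canvas; boxes that shrink below the area floor
    are dropped.
    """
    h, w = img.shape[:2]
    if angle_deg % 360 == 0:
        return img, list(boxes)
    # image rotation: positive angle rotates content counter-clockwise in
    # x-right/y-down coordinates when using the matching corner transform
    out = ndimage.rotate(img, angle_deg, axes=(1, 0), reshape=False,
                         order=1, mode="nearest")
    theta = math.radians(angle_deg)
    ct, st = math.cos(theta), math.sin(theta)
    cx, cy = w / 2.0, h / 2.0
    remapped = []
    for b in boxes:
        corners = np.array([[b.x1, b.y1], [b.x2, b.y1],
                            [b.x1, b.y2], [b.x2, b.y2]])
        dx = corners[:, 0] - cx
        dy = corners[:, 1] - cy
        rx = cx + ct * dx - st * dy
        ry = cy + st * dx + ct * dy
        x1, x2 = np.clip([rx.min(), rx.max()], 0, w)
        y1, y2 = np.clip([ry.min(), ry.max()], 0, h)
        if (x2 - x1) * (y2 - y1) >= min_box_area:
            remapped.append(Box(float(x1), float(y1), float(x2), float(y2)))
    return out, remapped


def mosaic(scenes, seed: int = 0) -> Scene:
    """Compose four same-size scenes into one around a random centre.

    Each quadrant receives a crop of the matching size taken from a random
    position of its source scene; boxes translate with the crop and clip
    to the quadrant.
    """
    if len(scenes) != 4:
        raise ValueError("mosaic needs exactly 4 scenes")
    sizes = {s.image.shape for s in scenes}
    if len(sizes) != 1:
        raise ValueError("mosaic scenes must share one image size")
    h, w = scenes[0].image.shape[:2]
    rng = np.random.default_rng(seed)
    cx = int(rng.uniform(0.3, 0.7) * w)
    cy = int(rng.uniform(0.3, 0.7) * h)
    canvas = np.zeros_like(scenes[0].image)
    out_boxes: list[Box] = []
    quads = [(0, 0, cx, cy), (cx, 0, w, cy), (0, cy, cx, h), (cx, cy, w, h)]
    for scene, (qx1, qy1, qx2, qy2) in zip(scenes, quads):
        qw, qh = qx2 - qx1, qy2 - qy1
        if qw == 0 or qh == 0:
            continue
        ox = int(rng.integers(0, w - qw + 1))
        oy = int(rng.integers(0, h - qh + 1))
        canvas[qy1:qy2, qx1:qx2] = scene.image[oy:oy + qh, ox:ox + qw]
        for b in scene.boxes:
            x1 = max(b.x1 - ox, 0.0) + qx1
            y1 = max(b.y1 - oy, 0.0) + qy1
            x2 = min(b.x2 - ox, float(qw)) + qx1
            y2 = min(b.y2 - oy, float(qh)) + qy1
            x1, x2 = max(x1, qx1), min(x2, qx2)
            y1, y2 = max(y1, qy1), min(y2, qy2)
            if x2 - x1 >= 2 and y2 - y1 >= 2:
                out_boxes.append(Box(x1, y1, x2, y2))
    return Scene(image=canvas, boxes=out_boxes, seed=seed)


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------

def make_dataset(cfg: SynthConfig, n_images: int, seed: int,
                 out_dir, val_fraction: float = 0.2) -> "pd.DataFrame":
    """Write PNG images plus GWHD-style CSV and YOLO-txt annotations.

    Returns the manifest DataFrame (image_id, split, n_boxes, paths); the
    same frame is saved as manifest.csv.  The train/val split takes the
    last ``val_fraction`` of images, so it partitions without overlap.
    """
    import pandas as pd
    from PIL import Image

    from .dataio import write_gwhd_csv, write_yolo_labels

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    n_val = int(round(n_images * val_fraction))
    rows, ann_rows = [], []
    for i in range(n_images):
        scene = sample_scene(cfg, seed=seed * 100003 + i)
        image_id = f"synth_{seed}_{i:05d}"
        png = out_dir / "images" / f"{image_id}.png"
        Image.fromarray(scene.image).save(png)
        write_yolo_labels(out_dir / "labels" / f"{image_id}.txt",
                          scene.boxes, cfg.image_size, cfg.image_size)
        split = "val" if i >= n_images - n_val else "train"
        rows.append({"image_id": image_id, "split": split,
                     "n_boxes": len(scene.boxes),
                     "image": str(png.relative_to(out_dir))})
        for b in scene.boxes:
            ann_rows.append((image_id, cfg.image_size, cfg.image_size, b))
    write_gwhd_csv(out_dir / "annotations.csv", ann_rows)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
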