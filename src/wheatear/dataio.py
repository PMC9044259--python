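"""Annotation readers/writers, YAML configuration and checkpointing.

Two on-disk annotation dialects are supported:

* GWHD-style CSV with columns ``image_id, width, height, bbox, source``
  where ``bbox`` is the string ``"[x, y, w, h]"`` in pixels;
* YOLO txt, one ``class cx cy w h`` line per box, all normalised to [0, 1].

Checkpoints are ``.npz`` archives of the model state dict plus a JSON
metadata blob (anchors, config, history).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boxes import Box


# ---------------------------------------------------------------------------
# GWHD-style CSV
# ---------------------------------------------------------------------------

def _parse_bbox(text: str, row_label) -> tuple[float, float, float, float]:
    try:
        vals = json.loads(text)
        if not isinstance(vals, list) or len(vals) != 4:
            raise ValueError
        return tuple(float(v) for v in vals)
    except (ValueError, TypeError) as err:
        raise ValueError(
            f"malformed bbox string {text!r} at row {row_label}") from err


def read_gwhd_csv(path) -> dict[str, dict]:
    """Parse annotations into {image_id: {width, height, boxes}}.

    ``bbox`` strings ``"[x, y, w, h]"`` become corner boxes
    (x, y, x+w, y+h).  Images listed with an empty/missing bbox keep an
    empty box list.
    """
    df = pd.read_csv(path)
    scenes: dict[str, dict] = {}
    for idx, row in df.iterrows():
        image_id = str(row["image_id"])
        entry = scenes.setdefault(image_id, {
            "width": int(row["width"]), "height": int(row["height"]),
            "boxes": []})
        raw = row.get("bbox")
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) \
                or str(raw).strip() == "":
            continue
        x, y, w, h = _parse_bbox(str(raw), idx)
        entry["boxes"].append(Box(x, y, x + w, y + h))
    return scenes


def write_gwhd_csv(path, rows, source: str = "synthetic"):
    """rows: iterable of (image_id, width, height, Box)."""
    records = []
    for image_id, width, height, box in rows:
        bbox = f"[{box.x1:g}, {box.y1:g}, {box.width:g}, {box.height:g}]"
        records.append({"image_id": image_id, "width": width,
                        "height": height, "bbox": bbox, "source": source})
    pd.DataFrame(records, columns=["image_id", "width", "height",
                                   "bbox", "source"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YOLO txt
# ---------------------------------------------------------------------------

def read_yolo_labels(path, image_w: int, image_h: int) -> list[Box]:
    """Normalised (class cx cy w h) lines -> pixel corner boxes."""
    boxes = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields")
        cls = int(parts[0])
        cx, cy, w, h = (float(p) for p in parts[1:])
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{path}:{ln}: normalised value {v} outside [0, 1]")
        boxes.append(Box((cx - w / 2) * image_w, (cy - h / 2) * image_h,
                         (cx + w / 2) * image_w, (cy + h / 2) * image_h,
                         class_id=cls))
    return boxes


def write_yolo_labels(path, boxes, image_w: int, image_h: int):
    lines = []
    for b in boxes:
        cx = (b.x1 + b.x2) / 2 / image_w
        cy = (b.y1 + b.y2) / 2 / image_h
        w = b.width / image_w
        h = b.height / image_h
        lines.append(f"{b.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# letterboxing for arbitrary image sizes
# ---------------------------------------------------------------------------

def letterbox(image: np.ndarray, multiple: int = 32,
              fill: int = 114) -> tuple[np.ndarray, int, int]:
    """Pad an HxWx3 image on the bottom/right to a multiple of ``multiple``.

    Aspect ratio is preserved (no resampling); returns (padded, pad_x,
    pad_y) — with corner-anchored padding the offsets are zero and box
    coordinates carry over unchanged, but they are returned for callers
    that want to crop detections back.
    """
    h, w = image.shape[:2]
    ph = (multiple - h % multiple) % multiple
    pw = (multiple - w % multiple) % multiple
    if ph == 0 and pw == 0:
        return image, 0, 0
    out = np.full((h + ph, w + pw, image.shape[2]), fill, dtype=image.dtype)
    out[:h, :w] = image
    return out, 0, 0


# ---------------------------------------------------------------------------
# detections output
# ---------------------------------------------------------------------------

def write_detections_csv(path, detections: dict[str, list[Box]]):
    """{image_id: boxes} -> CSV (image_id, x1, y1, x2, y2, confidence)."""
    rows = [{"image_id": image_id, "x1": b.x1, "y1": b.y1,
             "x2": b.x2, "y2": b.y2,
             "confidence": b.confidence if b.confidence is not None else 1.0}
            for image_id, boxes in detections.items() for b in boxes]
    pd.DataFrame(rows, columns=["image_id", "x1", "y1", "x2", "y2",
                                "confidence"]).to_csv(path, index=False)


def write_detections_json(path, detections: dict[str, list[Box]]):
    payload = {image_id: [{"x1": b.x1, "y1": b.y1, "x2": b.x2, "y2": b.y2,
                           "confidence": b.confidence}
                          for b in boxes]
               for image_id, boxes in detections.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# training configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters; the shipped defaults are the reference
    recipe (1024 input, batch 4, 100 epochs, lr 0.01 with cosine
    annealing to 0.2x, weight decay 5e-4, IoU threshold 0.5, Adam)."""

    input_size: int = 1024
    batch_size: int = 4
    epochs: int = 100
    learning_rate: float = 0.01
    weight_decay: float = 0.0005
    iou_threshold: float = 0.5
    cosine_annealing: float = 0.2   # final / initial learning-rate ratio
    optimizer: str = "adam"
    seed: int = 0
    width_multiple: float = 1.0
    mosaic_prob: float = 0.5
    augment_ops: tuple = ("scale", "mirror", "rotate", "saturation")

    def __post_init__(self):
        if not 0 < self.iou_threshold < 1:
            raise ValueError("iou_threshold must be in (0, 1)")
        for name in ("input_size", "batch_size", "epochs", "learning_rate",
                     "weight_decay", "cosine_annealing"):
            if getattr(self, name) <= 0 and name not in ("weight_decay",):
                raise ValueError(f"{name} must be positive")

    def save(self, path):
        data = asdict(self)
        data["augment_ops"] = list(self.augment_ops)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def load(cls, path) -> "TrainConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "augment_ops" in data:
            data["augment_ops"] = tuple(data["augment_ops"])
        return cls(**data)


def cosine_lr(cfg: TrainConfig, epoch: int) -> float:
    """Cosine-annealed learning rate for a 0-based epoch index.

    Decays from the initial rate to ``cosine_annealing`` times it at the
    final epoch.
    """
    lr0 = cfg.learning_rate
    lrf = cfg.cosine_annealing * lr0
    if cfg.epochs == 1:
        return lr0
    t = epoch / (cfg.epochs - 1)
    return lrf + 0.5 * (lr0 - lrf) * (1.0 + np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, meta: dict | None = None):
    state = model.state_dict()
    meta = dict(meta or {})
    meta["anchors"] = model.anchors.tolist()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, model) -> dict:
    """Restore parameters/buffers in-place; returns the metadata dict."""
    from .neck import AnchorSet
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.load_state_dict(state)
    if "anchors" in meta:
        model.anchors = AnchorSet(meta["anchors"])
    return meta
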