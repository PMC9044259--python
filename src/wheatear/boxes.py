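"""Axis-aligned boxes in half-open pixel coordinates (x right, y down).

A box is (x1, y1, x2, y2) with x2 > x1 and y2 > y1; area is
(x2-x1)*(y2-y1) with no +1 convention, matching normalised YOLO labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Box:
    x1: float
    y1: float
    x2: float
    y2: float
    confidence: float | None = None
    class_id: int = 0

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"degenerate box ({self.x1}, {self.y1}, {self.x2}, {self.y2}):"
                " width and height must be positive")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x1 + self.x2) / 2, (self.y1 + self.y2) / 2

    def as_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    def shifted(self, dx: float, dy: float) -> "Box":
        return Box(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy,
                   self.confidence, self.class_id)


def as_box(b) -> Box:
    """Coerce a Box, 4-sequence or array row into a Box."""
    if isinstance(b, Box):
        return b
    seq = [float(v) for v in np.asarray(b).ravel()[:4]]
    return Box(*seq)


def boxes_to_array(boxes) -> np.ndarray:
    """(M, 4) float array from a Box iterable (empty-safe)."""
    if len(boxes) == 0:
        return np.zeros((0, 4))
    return np.array([[b.x1, b.y1, b.x2, b.y2] for b in boxes], dtype=np.float64)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M, 4) and (K, 4) corner arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-12)
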