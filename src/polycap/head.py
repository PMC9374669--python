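"""Detection head: grid decoding, confidence filtering and non-maximum suppression.

The backbone emits a ``G x G x (3*5)`` grid (``G = 4`` for 240 px input).
Each grid cell carries 3 candidate boxes parameterised by 5 raw elements
``(score, tx, ty, tw, th)``.  Decoding follows the usual invertible
convention for grid detectors: sigmoid cell offsets for the centre,
exponential scaling of per-cell anchor priors for width/height.  Decoded
boxes use the upper-left-corner ``(x, y, w, h)`` convention, 0-based,
half-open pixel intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "BoundingBox",
    "ProposalSet",
    "HeadConfig",
    "decode_grid",
    "encode_boxes",
    "iou",
    "confidence_filter",
    "nms",
    "classify_frame",
]

DEFAULT_ANCHORS = ((24.0, 24.0), (60.0, 60.0), (120.0, 120.0))
ELEMENTS_PER_BOX = 5  # (score, x, y, w, h)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: upper-left corner ``(x, y)``, extent ``(w, h)``, confidence."""

    x: float
    y: float
    w: float
    h: float
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box extent must be positive, got w={self.w}, h={self.h}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.score}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def clipped(self, width: float, height: float) -> "BoundingBox | None":
        """Clip to ``[0, width) x [0, height)``; ``None`` if nothing remains."""
        x1 = min(max(self.x, 0.0), width)
        y1 = min(max(self.y, 0.0), height)
        x2 = min(max(self.x2, 0.0), width)
        y2 = min(max(self.y2, 0.0), height)
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            return None
        return BoundingBox(x1, y1, x2 - x1, y2 - y1, self.score)


@dataclass
class ProposalSet:
    """A bag of candidate boxes attached to one source frame."""

    boxes: list[BoundingBox] = field(default_factory=list)
    source_frame_id: str | None = None

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)


@dataclass(frozen=True)
class HeadConfig:
    """Decoding and filtering parameters.

    ``score_threshold`` is the confidence cut (default 0.65) applied as
    ``score >= threshold`` (inclusive); ``nms_iou`` is the separate overlap
    threshold governing suppression.
    """

    score_threshold: float = 0.65
    nms_iou: float = 0.5
    anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    image_size: int = 240

    def __post_init__(self) -> None:
        if len(self.anchors) != 3:
            raise ValueError(f"exactly 3 anchors required, got {len(self.anchors)}")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must lie in [0, 1]")
        if not (0.0 <= self.nms_iou <= 1.0):
            raise ValueError("nms_iou must lie in [0, 1]")

    def scaled(self, image_size: int) -> "HeadConfig":
        """Anchors rescaled proportionally for a different frame size."""
        f = image_size / self.image_size
        anchors = tuple((w * f, h * f) for (w, h) in self.anchors)
        return replace(self, anchors=anchors, image_size=image_size)


def decode_grid(grid: np.ndarray, config: HeadConfig,
                source_frame_id: str | None = None) -> ProposalSet:
    """Decode a raw ``G x G x 15`` grid into one proposal per cell/anchor.

    Raw channel layout per anchor: ``(score, tx, ty, tw, th)``.  The centre
    is ``(col + sigmoid(tx)) * cell`` / ``(row + sigmoid(ty)) * cell``; width
    and height are ``anchor * exp(t)``.  Boxes are clipped to the frame;
    zero-area boxes after clipping are dropped (cannot occur for finite raw
    values since the centre always lies inside the frame).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 3 or grid.shape[2] != len(config.anchors) * ELEMENTS_PER_BOX:
        raise ValueError(
            f"expected a (G, G, {len(config.anchors) * ELEMENTS_PER_BOX}) grid, "
            f"got shape {grid.shape}"
        )
    n_rows, n_cols, _ = grid.shape
    cell_h = config.image_size / n_rows
    cell_w = config.image_size / n_cols

    raw = grid.reshape(n_rows, n_cols, len(config.anchors), ELEMENTS_PER_BOX)
    boxes: list[BoundingBox] = []
    for row in range(n_rows):
        for col in range(n_cols):
            for a, (aw, ah) in enumerate(config.anchors):
                s, tx, ty, tw, th = raw[row, col, a]
                score = float(_sigmoid(s))
                cx = (col + float(_sigmoid(tx))) * cell_w
                cy = (row + float(_sigmoid(ty))) * cell_h
                w = aw * float(np.exp(tw))
                h = ah * float(np.exp(th))
                if w <= 0 or h <= 0:  # numerically collapsed box
                    continue
                box = BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h, score)
                clipped = box.clipped(config.image_size, config.image_size)
                if clipped is not None:
                    boxes.append(clipped)
    return ProposalSet(boxes=boxes, source_frame_id=source_frame_id)


def encode_boxes(boxes: list[BoundingBox], grid_shape: tuple[int, int],
                 config: HeadConfig) -> np.ndarray:
    """Inverse of :func:`decode_grid` for unclipped boxes.

    Places each box into the cell containing its centre, choosing the anchor
    with the best shape-only overlap, and writes the raw ``(score, tx, ty,
    tw, th)`` elements.  Used for loss-target construction and round-trip
    testing.  Unoccupied slots hold a large negative raw score (decodes to
    confidence ~0).
    """
    n_rows, n_cols = grid_shape
    cell_h = config.image_size / n_rows
    cell_w = config.image_size / n_cols
    grid = np.zeros((n_rows, n_cols, len(config.anchors), ELEMENTS_PER_BOX))
    grid[..., 0] = -1e9
    eps = 1e-12
    for box in boxes:
        cx, cy = box.center
        col = min(int(cx / cell_w), n_cols - 1)
        row = min(int(cy / cell_h), n_rows - 1)
        a = best_anchor(box.w, box.h, config.anchors)
        ox = np.clip(cx / cell_w - col, eps, 1 - eps)
        oy = np.clip(cy / cell_h - row, eps, 1 - eps)
        s = np.clip(box.score, eps, 1 - eps)
        grid[row, col, a] = (
            np.log(s / (1 - s)),
            np.log(ox / (1 - ox)),
            np.log(oy / (1 - oy)),
            np.log(box.w / config.anchors[a][0]),
            np.log(box.h / config.anchors[a][1]),
        )
    return grid.reshape(n_rows, n_cols, -1)


def best_anchor(w: float, h: float, anchors: tuple[tuple[float, float], ...]) -> int:
    """Index of the anchor whose shape best overlaps ``(w, h)`` when co-centred."""
    best, best_iou = 0, -1.0
    for i, (aw, ah) in enumerate(anchors):
        inter = min(w, aw) * min(h, ah)
        union = w * h + aw * ah - inter
        v = inter / union
        if v > best_iou:
            best, best_iou = i, v
    return best


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def confidence_filter(proposals: ProposalSet, threshold: float) -> ProposalSet:
    """Keep exactly the boxes with ``score >= threshold`` (inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    kept = [b for b in proposals.boxes if b.score >= threshold]
    return ProposalSet(boxes=kept, source_frame_id=proposals.source_frame_id)


def nms(proposals: ProposalSet, nms_iou: float) -> ProposalSet:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-confidence remaining box and discards boxes
    overlapping it with ``iou >= nms_iou``.  Ties in confidence are broken
    by lower original index.  Survivors come out sorted by descending
    confidence.
    """
    order = sorted(range(len(proposals.boxes)),
                   key=lambda i: (-proposals.boxes[i].score, i))
    kept: list[BoundingBox] = []
    suppressed = [False] * len(order)
    for pos, i in enumerate(order):
        if suppressed[pos]:
            continue
        top = proposals.boxes[i]
        kept.append(top)
        for later_pos in range(pos + 1, len(order)):
            if suppressed[later_pos]:
                continue
            if iou(top, proposals.boxes[order[later_pos]]) >= nms_iou:
                suppressed[later_pos] = True
    return ProposalSet(boxes=kept, source_frame_id=proposals.source_frame_id)


def classify_frame(detections: ProposalSet) -> str:
    """``"significant"`` iff at least one (already filtered) box survives."""
    return "significant" if len(detections.boxes) > 0 else "insignificant"
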