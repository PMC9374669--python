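"""Shared annotated-frame record used by the generator, trainer and simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .head import BoundingBox

__all__ = ["AnnotatedImage", "WLI", "NBI"]

WLI = "WLI"
NBI = "NBI"


@dataclass
class AnnotatedImage:
    """A frame with ground-truth boxes and acquisition metadata.

    ``pixels`` is ``(H, W, 3)`` float in [0, 1].  The class label is derived:
    a frame is a polyp frame iff it carries at least one box.  ``meta`` holds
    generator-internal extras (e.g. vessel masks) and is never serialized.
    """

    pixels: np.ndarray
    boxes: list[BoundingBox] = field(default_factory=list)
    patient_id: str = "p0"
    modality: str = WLI
    cleanliness: int = 0
    frame_id: str | None = None
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.modality not in (WLI, NBI):
            raise ValueError(f"modality must be WLI or NBI, got {self.modality!r}")
        h, w = self.pixels.shape[:2]
        for b in self.boxes:
            if b.x < 0 or b.y < 0 or b.x2 > w or b.y2 > h:
                raise ValueError(f"box {b} exceeds image bounds {w}x{h}")

    @property
    def label(self) -> str:
        return "polyp" if self.boxes else "normal"

    @property
    def size(self) -> int:
        return self.pixels.shape[0]
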