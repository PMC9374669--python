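"""Seeded generator of endoscopy-like frames with ground-truth polyp boxes.

The textures are explicitly artificial — smooth reddish mucosa, curvilinear
vessel strokes, elliptical protrusions with a brightness dome and specular
highlight, debris blobs for poor cleanliness — tuned only to give a grid
detector something structured to learn, not to look photorealistic.
Per-patient style parameters (base hue, vessel density) make patient-wise
splitting meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .head import BoundingBox
from .records import NBI, WLI, AnnotatedImage

__all__ = ["SynthConfig", "PatientStyle", "generate_frame", "render_nbi", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 10
    frames_per_patient: int = 20
    polyp_prevalence: float = 0.5
    polyp_size_range: tuple[float, float] = (24.0, 110.0)  # at 240 px reference scale
    polyps_per_frame: int = 1
    cleanliness_levels: int = 3
    frame_size: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.frames_per_patient,
               self.polyps_per_frame, self.cleanliness_levels) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.polyp_size_range
        if not (0 < lo <= hi < 240):
            raise ValueError("polyp_size_range must lie within (0, 240)")
        if not (0.0 <= self.polyp_prevalence <= 1.0):
            raise ValueError("polyp_prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class PatientStyle:
    """Per-patient appearance parameters; drawn once per patient id."""

    base_color: tuple[float, float, float]
    vessel_density: float
    texture_scale: float

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "PatientStyle":
        base = (0.55 + 0.25 * rng.random(),   # red
                0.18 + 0.18 * rng.random(),   # green
                0.12 + 0.14 * rng.random())   # blue
        return cls(base_color=base,
                   vessel_density=0.5 + rng.random(),
                   texture_scale=0.7 + 0.6 * rng.random())


def _mucosa(rng: np.random.Generator, size: int, style: PatientStyle) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float64)
    sigma = size / 14.0 * style.texture_scale
    for c, base in enumerate(style.base_color):
        noise = gaussian_filter(rng.standard_normal((size, size)), sigma)
        noise /= max(np.abs(noise).max(), 1e-9)
        img[..., c] = base + 0.10 * noise
    # radial vignette: dimmer toward the frame edge, like a dome-lit lumen
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - size / 2, xx - size / 2) / (size / 2)
    img *= (1.0 - 0.45 * np.clip(r, 0, 1) ** 2)[..., None]
    return img


def _vessels(rng: np.random.Generator, size: int, style: PatientStyle) -> np.ndarray:
    """Accumulated stroke intensity in [0, 1] from random quadratic curves."""
    canvas = np.zeros((size, size), dtype=np.float64)
    n = rng.poisson(6 * style.vessel_density) + 2
    for _ in range(n):
        p = rng.random((3, 2)) * size
        t = np.linspace(0, 1, 4 * size)
        pts = ((1 - t) ** 2)[:, None] * p[0] + (2 * t * (1 - t))[:, None] * p[1] \
            + (t ** 2)[:, None] * p[2]
        ij = np.clip(pts.astype(int), 0, size - 1)
        canvas[ij[:, 1], ij[:, 0]] = 1.0
    canvas = gaussian_filter(canvas, size / 240.0)
    peak = canvas.max()
    return canvas / peak if peak > 0 else canvas


def _stamp_polyp(rng: np.random.Generator, img: np.ndarray, size: int,
                 cfg: SynthConfig) -> tuple[BoundingBox, np.ndarray]:
    """Draw one elliptical protrusion; return its tight box and pixel mask."""
    scale = size / 240.0
    lo, hi = cfg.polyp_size_range
    diameter = math.exp(rng.uniform(math.log(lo), math.log(hi))) * scale
    a = diameter / 2.0
    b = a * (1.0 - 0.8 * rng.random())          # eccentricity 0 .. 0.8
    b = max(b, 2.0)
    theta = rng.uniform(0, math.pi)
    margin = max(a, b) + 2
    cx = rng.uniform(margin, size - margin)
    cy = rng.uniform(margin, size - margin)

    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    xr = dx * math.cos(theta) + dy * math.sin(theta)
    yr = -dx * math.sin(theta) + dy * math.cos(theta)
    q = (xr / a) ** 2 + (yr / b) ** 2
    mask = q <= 1.0
    dome = np.clip(1.0 - q, 0.0, 1.0) ** 0.7

    tint = np.array([0.30 + 0.15 * rng.random(),
                     0.16 + 0.10 * rng.random(),
                     0.12 + 0.08 * rng.random()])
    img += dome[..., None] * tint
    # specular highlight offset toward the light axis
    hx = cx + 0.3 * a * (rng.random() - 0.5)
    hy = cy + 0.3 * b * (rng.random() - 0.5)
    hl = np.exp(-((xx - hx) ** 2 + (yy - hy) ** 2) / (2 * (0.18 * diameter + 1e-9) ** 2))
    img += (hl * dome)[..., None] * 0.35
    if rng.random() < 0.3:  # pedunculated: short stalk below the head
        sx = cx + a * math.sin(theta)
        sy = cy + b * math.cos(theta)
        stalk = np.exp(-(((xx - sx) / (0.35 * a)) ** 2 + ((yy - sy) / (0.8 * b)) ** 2))
        img += stalk[..., None] * tint * 0.5

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = BoundingBox(x=float(cols[0]), y=float(rows[0]),
                      w=float(cols[-1] - cols[0] + 1),
                      h=float(rows[-1] - rows[0] + 1), score=1.0)
    return box, mask


def _debris(rng: np.random.Generator, img: np.ndarray, size: int, grade: int) -> None:
    for _ in range(3 * grade):
        r = rng.uniform(0.02, 0.06) * size
        cx, cy = rng.uniform(0, size, 2)
        yy, xx = np.mgrid[0:size, 0:size]
        blob = np.exp(-(((xx - cx) / r) ** 2 + ((yy - cy) / (r * rng.uniform(0.5, 1.5))) ** 2))
        color = np.array([0.45, 0.38, 0.15]) * rng.uniform(0.7, 1.2)
        img[:] = img * (1 - 0.8 * blob[..., None]) + 0.8 * blob[..., None] * color


def generate_frame(rng: np.random.Generator, has_polyp: bool, cleanliness: int = 0,
                   modality: str = WLI, *, config: SynthConfig | None = None,
                   style: PatientStyle | None = None, patient_id: str = "p0",
                   frame_id: str | None = None) -> AnnotatedImage:
    """Render one frame, fully determined by the generator state.

    Polyp frames carry 1..``polyps_per_frame`` protrusions, each with a
    tight pixel-accurate bounding box.  Higher cleanliness grades add
    occluding debris.
    """
    cfg = config or SynthConfig()
    size = cfg.frame_size
    if style is None:
        style = PatientStyle.sample(rng)
    img = _mucosa(rng, size, style)
    vessels = _vessels(rng, size, style)
    img[..., 0] -= 0.22 * vessels
    img[..., 1] -= 0.10 * vessels
    img[..., 2] -= 0.06 * vessels

    boxes: list[BoundingBox] = []
    if has_polyp:
        n = 1 if cfg.polyps_per_frame == 1 else int(rng.integers(1, cfg.polyps_per_frame + 1))
        for _ in range(n):
            box, _mask = _stamp_polyp(rng, img, size, cfg)
            boxes.append(box)
    _debris(rng, img, size, int(cleanliness))
    img += 0.01 * rng.standard_normal(img.shape)
    frame = AnnotatedImage(
        pixels=np.clip(img, 0.0, 1.0),
        boxes=boxes,
        patient_id=patient_id,
        modality=WLI,
        cleanliness=int(cleanliness),
        frame_id=frame_id,
        meta={"vessel_mask": vessels > 0.35},
    )
    if modality == NBI:
        frame = render_nbi(frame)
    return frame


def render_nbi(frame: AnnotatedImage) -> AnnotatedImage:
    """Deterministic WLI -> NBI colour transform; geometry is untouched.

    Red is attenuated; green and blue are contrast-stretched around their
    means with fine detail (vessel strokes) amplified by an unsharp mask,
    so vessel-to-background contrast strictly increases.
    """
    if frame.modality != WLI:
        raise ValueError("render_nbi expects a WLI frame")
    px = frame.pixels.astype(np.float64).copy()
    px[..., 0] *= 0.30
    for c in (1, 2):
        ch = px[..., c]
        detail = ch - gaussian_filter(ch, 2.0)
        stretched = (ch - ch.mean()) * 1.7 + ch.mean() * 0.95 + 1.2 * detail
        px[..., c] = stretched
    return AnnotatedImage(
        pixels=np.clip(px, 0.0, 1.0),
        boxes=list(frame.boxes),
        patient_id=frame.patient_id,
        modality=NBI,
        cleanliness=frame.cleanliness,
        frame_id=frame.frame_id,
        meta=dict(frame.meta),
    )


def generate_dataset(config: SynthConfig) -> list[AnnotatedImage]:
    """``n_patients x frames_per_patient`` frames with per-patient style."""
    rng = np.random.default_rng(config.seed)
    frames: list[AnnotatedImage] = []
    for p in range(config.n_patients):
        pid = f"patient{p:04d}"
        style = PatientStyle.sample(rng)
        for f in range(config.frames_per_patient):
            has_polyp = bool(rng.random() < config.polyp_prevalence)
            grade = int(rng.integers(0, config.cleanliness_levels))
            frames.append(generate_frame(
                rng, has_polyp, cleanliness=grade, config=config, style=style,
                patient_id=pid, frame_id=f"{pid}/f{f:04d}"))
    return frames
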