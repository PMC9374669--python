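"""Dataset protocol and detector training.

The protocol mirrors the study design: class-balance polyp frames against
an equal-count sample of normal frames, augment tenfold with random
rotation / scaling / translation / flipping / cropping (never cropping a
polyp out), and split by patient 80/10/10 with balanced validation and
test sets.  Training uses a grid-detection composite loss (squared-error
localization on matched cells/anchors, cross-entropy objectness,
down-weighted no-object term) optimised with Adam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from scipy.special import expit as _sigmoid

from .head import BoundingBox, HeadConfig, best_anchor
from .net.network import Network
from .records import AnnotatedImage

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "DatasetSplit",
    "balance_dataset",
    "augment",
    "split_by_patient",
    "train_detector",
    "detection_loss",
    "mirror_frame",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Parameter ranges for the random transform composition."""

    rotation_deg: tuple[float, float] = (-180.0, 180.0)
    scale: tuple[float, float] = (0.8, 1.2)
    translation_frac: float = 0.10
    flip: bool = True
    crop_area_min: float = 0.80   # crop retains at least this fraction of area
    max_crop_retries: int = 10
    min_box_area_kept: float = 0.30  # a gt box must keep this fraction of its area

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(rotation_deg=(0.0, 0.0), scale=(1.0, 1.0), translation_frac=0.0,
                   flip=False, crop_area_min=1.0)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 20
    step_size: float = 1e-3
    epochs: int = 30
    augmentation_factor: int = 10
    seed: int = 0
    loss_weights: tuple[float, float, float] = (5.0, 1.0, 0.5)  # loc, obj, no-obj
    patience: int = 10
    mirror: bool = True
    lr_decay: float = 1.0  # multiplicative per-epoch step-size decay

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.step_size < 0 or self.augmentation_factor < 1:
            raise ValueError("invalid training configuration")


@dataclass
class DatasetSplit:
    train: list[AnnotatedImage]
    validation: list[AnnotatedImage]
    test: list[AnnotatedImage]
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)


# ---------------------------------------------------------------------------
# dataset protocol


def balance_dataset(polyp_images: list[AnnotatedImage],
                    normal_pool: list[AnnotatedImage],
                    rng: np.random.Generator) -> list[AnnotatedImage]:
    """Polyp frames plus an equal-count random sample of normal frames."""
    if not polyp_images:
        return []
    if len(normal_pool) < len(polyp_images):
        raise ValueError(
            f"need at least {len(polyp_images)} normal frames, got {len(normal_pool)}"
        )
    idx = rng.choice(len(normal_pool), size=len(polyp_images), replace=False)
    return list(polyp_images) + [normal_pool[i] for i in sorted(idx)]


def _forward_matrix(size: int, angle: float, scale: float, tx: float, ty: float,
                    flip_x: bool, flip_y: bool,
                    crop: tuple[float, float, float] | None) -> np.ndarray:
    """Homogeneous forward map in (x, y) convention, source -> output pixels."""
    c = (size - 1) / 2.0

    def mat(a, b, cc, d, e, f):
        return np.array([[a, b, cc], [d, e, f], [0, 0, 1.0]])

    recenter = mat(1, 0, -c, 0, 1, -c)
    fl = mat(-1.0 if flip_x else 1.0, 0, 0, 0, -1.0 if flip_y else 1.0, 0)
    th = math.radians(angle)
    rot = mat(math.cos(th), -math.sin(th), 0, math.sin(th), math.cos(th), 0)
    sc = mat(scale, 0, 0, 0, scale, 0)
    back = mat(1, 0, c + tx, 0, 1, c + ty)
    m = back @ sc @ rot @ fl @ recenter
    if crop is not None:
        x0, y0, w = crop
        zoom = size / w
        m = mat(zoom, 0, -x0 * zoom, 0, zoom, -y0 * zoom) @ m
    return m


def _warp_image(pixels: np.ndarray, m_fwd: np.ndarray) -> np.ndarray:
    """Apply the forward (x, y) map to an (H, W, 3) image via inverse mapping."""
    if np.allclose(m_fwd, np.eye(3)):
        return pixels.copy()
    swap = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1.0]])
    m_yx = swap @ m_fwd @ swap
    inv = np.linalg.inv(m_yx)
    out = np.empty_like(pixels)
    for ch in range(pixels.shape[2]):
        out[..., ch] = affine_transform(pixels[..., ch], inv[:2, :2], offset=inv[:2, 2],
                                        order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _transform_box(box: BoundingBox, m_fwd: np.ndarray, size: int) -> BoundingBox | None:
    corners = np.array([[box.x, box.y, 1.0], [box.x2, box.y, 1.0],
                        [box.x, box.y2, 1.0], [box.x2, box.y2, 1.0]]).T
    moved = m_fwd @ corners
    xs, ys = moved[0], moved[1]
    w = xs.max() - xs.min()
    h = ys.max() - ys.min()
    if w <= 0 or h <= 0:
        return None
    return BoundingBox(float(xs.min()), float(ys.min()), float(w), float(h),
                       box.score).clipped(size, size)


def _sample_transform(rng: np.random.Generator, size: int, cfg: AugmentConfig,
                      with_crop: bool) -> np.ndarray:
    angle = rng.uniform(*cfg.rotation_deg)
    scale = rng.uniform(*cfg.scale)
    t = cfg.translation_frac * size
    tx, ty = (rng.uniform(-t, t), rng.uniform(-t, t)) if t > 0 else (0.0, 0.0)
    flip_x = cfg.flip and bool(rng.integers(2))
    flip_y = cfg.flip and bool(rng.integers(2))
    crop = None
    if with_crop and cfg.crop_area_min < 1.0:
        frac = rng.uniform(math.sqrt(cfg.crop_area_min), 1.0)
        w = frac * size
        x0 = rng.uniform(0, size - w)
        y0 = rng.uniform(0, size - w)
        crop = (x0, y0, w)
    return _forward_matrix(size, angle, scale, tx, ty, flip_x, flip_y, crop)


def _augment_one(frame: AnnotatedImage, rng: np.random.Generator,
                 cfg: AugmentConfig, tag: str) -> AnnotatedImage:
    size = frame.pixels.shape[0]
    for attempt in range(cfg.max_crop_retries + 1):
        with_crop = attempt < cfg.max_crop_retries
        m = _sample_transform(rng, size, cfg, with_crop)
        new_boxes: list[BoundingBox] = []
        ok = True
        for box in frame.boxes:
            moved = _transform_box(box, m, size)
            if moved is None or moved.area < cfg.min_box_area_kept * box.area:
                ok = False
                break
            new_boxes.append(moved)
        if ok:
            break
    else:  # pragma: no cover - retries always terminate via the flip-only fallback
        m = np.eye(3)
        new_boxes = list(frame.boxes)
    return AnnotatedImage(
        pixels=_warp_image(frame.pixels, m),
        boxes=new_boxes,
        patient_id=frame.patient_id,
        modality=frame.modality,
        cleanliness=frame.cleanliness,
        frame_id=f"{frame.frame_id}/{tag}" if frame.frame_id else None,
    )


def augment(dataset: list[AnnotatedImage], factor: int, rng: np.random.Generator,
            config: AugmentConfig | None = None) -> list[AnnotatedImage]:
    """``factor`` random variants per frame; polyp boxes are never cropped out.

    A sampled crop that would drop any ground-truth box below the retained-
    area floor is rejected and resampled; after bounded retries the variant
    falls back to a non-cropping transform.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    cfg = config or AugmentConfig()
    out: list[AnnotatedImage] = []
    for frame in dataset:
        for k in range(factor):
            out.append(_augment_one(frame, rng, cfg, tag=f"aug{k}"))
    return out


def split_by_patient(dataset: list[AnnotatedImage],
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     rng: np.random.Generator | None = None) -> DatasetSplit:
    """Assign whole patients to train/validation/test, then balance val/test.

    Patients (never individual frames) are placed greedily after a seeded
    shuffle so achieved image fractions track the targets.  Validation and
    test are rebalanced by down-sampling their majority class; a part left
    without both classes is an error.
    """
    rng = rng or np.random.default_rng(0)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients: dict[str, list[AnnotatedImage]] = {}
    for frame in dataset:
        patients.setdefault(frame.patient_id, []).append(frame)
    if len(patients) < 3:
        raise ValueError(f"need at least 3 distinct patients, got {len(patients)}")

    ids = sorted(patients)
    rng.shuffle(ids)
    total = len(dataset)
    targets = [f * total for f in fractions]
    assigned: list[list[AnnotatedImage]] = [[], [], []]
    counts = [0, 0, 0]
    for rank, pid in enumerate(ids):
        if rank < 3:
            part = rank  # every part gets at least one patient
        else:
            deficits = [targets[i] - counts[i] for i in range(3)]
            part = int(np.argmax(deficits))
        assigned[part].extend(patients[pid])
        counts[part] += len(patients[pid])

    def rebalance(frames: list[AnnotatedImage], part_name: str) -> list[AnnotatedImage]:
        polyp = [f for f in frames if f.label == "polyp"]
        normal = [f for f in frames if f.label == "normal"]
        if not polyp or not normal:
            raise ValueError(f"cannot class-balance the {part_name} set: "
                             f"{len(polyp)} polyp vs {len(normal)} normal frames")
        n = min(len(polyp), len(normal))
        keep_p = [polyp[i] for i in sorted(rng.choice(len(polyp), n, replace=False))]
        keep_n = [normal[i] for i in sorted(rng.choice(len(normal), n, replace=False))]
        return keep_p + keep_n

    return DatasetSplit(
        train=assigned[0],
        validation=rebalance(assigned[1], "validation"),
        test=rebalance(assigned[2], "test"),
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# loss and training loop


def build_targets(frames: list[AnnotatedImage], grid: tuple[int, int],
                  head: HeadConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-batch objectness mask and raw-space localization targets."""
    n_rows, n_cols = grid
    n_a = len(head.anchors)
    cell_w = head.image_size / n_cols
    cell_h = head.image_size / n_rows
    obj = np.zeros((len(frames), n_rows, n_cols, n_a), dtype=np.float32)
    loc = np.zeros((len(frames), n_rows, n_cols, n_a, 4), dtype=np.float32)
    for n, frame in enumerate(frames):
        for box in frame.boxes:
            cx, cy = box.center
            col = min(int(cx / cell_w), n_cols - 1)
            row = min(int(cy / cell_h), n_rows - 1)
            a = best_anchor(box.w, box.h, head.anchors)
            obj[n, row, col, a] = 1.0
            loc[n, row, col, a] = (
                cx / cell_w - col,
                cy / cell_h - row,
                math.log(box.w / head.anchors[a][0]),
                math.log(box.h / head.anchors[a][1]),
            )
    return obj, loc


def detection_loss(raw: np.ndarray, frames: list[AnnotatedImage],
                   head: HeadConfig, weights: tuple[float, float, float]
                   ) -> tuple[float, np.ndarray]:
    """Composite grid loss and its gradient with respect to the raw output.

    Squared error on sigmoid centre offsets and log size ratios for matched
    anchors (weight ``w_loc``), binary cross-entropy objectness with weight
    ``w_obj`` on matched and ``w_noobj`` on unmatched slots.  Averaged over
    the batch.
    """
    w_loc, w_obj, w_noobj = weights
    n, gr, gc, ch = raw.shape
    n_a = ch // 5
    r = raw.reshape(n, gr, gc, n_a, 5).astype(np.float64)
    obj, loc = build_targets(frames, (gr, gc), head)

    p = _sigmoid(r[..., 0])
    eps = 1e-9
    w_bce = np.where(obj > 0, w_obj, w_noobj)
    bce = -(obj * np.log(p + eps) + (1 - obj) * np.log(1 - p + eps))
    loss_obj = float((w_bce * bce).sum()) / n

    sxy = _sigmoid(r[..., 1:3])
    d_xy = sxy - loc[..., 0:2]
    d_wh = r[..., 3:5] - loc[..., 2:4]
    mask = obj[..., None]
    loss_loc = float(w_loc * ((mask * d_xy ** 2).sum() + (mask * d_wh ** 2).sum())) / n

    grad = np.zeros_like(r)
    grad[..., 0] = w_bce * (p - obj) / n
    grad[..., 1:3] = 2.0 * w_loc * mask * d_xy * sxy * (1 - sxy) / n
    grad[..., 3:5] = 2.0 * w_loc * mask * d_wh / n
    return loss_obj + loss_loc, grad.reshape(raw.shape).astype(np.float32)


def mirror_frame(frame: AnnotatedImage, flip_x: bool, flip_y: bool) -> AnnotatedImage:
    """Horizontal/vertical mirroring with consistent box coordinates."""
    if not (flip_x or flip_y):
        return frame
    px = frame.pixels
    size_y, size_x = px.shape[:2]
    if flip_x:
        px = px[:, ::-1]
    if flip_y:
        px = px[::-1]
    boxes = []
    for b in frame.boxes:
        x = size_x - b.x2 if flip_x else b.x
        y = size_y - b.y2 if flip_y else b.y
        boxes.append(BoundingBox(x, y, b.w, b.h, b.score))
    return replace_pixels(frame, np.ascontiguousarray(px), boxes)


def replace_pixels(frame: AnnotatedImage, pixels: np.ndarray,
                   boxes: list[BoundingBox]) -> AnnotatedImage:
    return AnnotatedImage(pixels=pixels, boxes=boxes, patient_id=frame.patient_id,
                          modality=frame.modality, cleanliness=frame.cleanliness,
                          frame_id=frame.frame_id)


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (name, op, key)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {name: np.zeros_like(getattr(op, key)) for name, op, key in params}
        self.v = {name: np.zeros_like(getattr(op, key)) for name, op, key in params}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, op, key in self.params:
            g = op.grads.get(key)
            if g is None:
                continue
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            new = getattr(op, key) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            setattr(op, key, new.astype(getattr(op, key).dtype))


def _batch_loss(network: Network, frames: list[AnnotatedImage], head: HeadConfig,
                weights, training: bool) -> tuple[float, np.ndarray | None]:
    x = np.stack([f.pixels for f in frames])
    raw = network.forward_batch(x, training=training)
    loss, grad = detection_loss(raw, frames, head, weights)
    return loss, grad


def train_detector(network: Network, split: DatasetSplit, config: TrainConfig,
                   head: HeadConfig | None = None,
                   ) -> tuple[Network, dict[str, list[float]]]:
    """Adam training with random mirroring; returns best-on-validation weights.

    History records per-epoch mean training loss and validation loss.
    Non-finite loss aborts with a diagnostic.
    """
    if not split.train:
        raise ValueError("training set is empty")
    size = split.train[0].pixels.shape[0]
    head = (head or HeadConfig()).scaled(size) if head is None or head.image_size != size \
        else head
    rng = np.random.default_rng(config.seed)
    opt = _Adam(network.parameters(), lr=config.step_size)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = {k: v.copy() for k, v in network.state_dict().items()}
    since_best = 0

    for epoch in range(config.epochs):
        opt.lr = config.step_size * config.lr_decay ** epoch
        order = rng.permutation(len(split.train))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [split.train[i] for i in order[start:start + config.batch_size]]
            if config.mirror:
                batch = [mirror_frame(f, bool(rng.integers(2)), bool(rng.integers(2)))
                         for f in batch]
            loss, grad = _batch_loss(network, batch, head, config.loss_weights,
                                     training=True)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at epoch {epoch}"
                )
            network.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))

        if split.validation:
            val_losses = []
            for start in range(0, len(split.validation), config.batch_size):
                batch = split.validation[start:start + config.batch_size]
                loss, _ = _batch_loss(network, batch, head, config.loss_weights,
                                      training=False)
                val_losses.append(loss * len(batch))
            val = float(np.sum(val_losses) / len(split.validation))
        else:
            val = history["train_loss"][-1]
        history["val_loss"].append(val)

        if val < best_val - 1e-12:
            best_val = val
            best_state = {k: v.copy() for k, v in network.state_dict().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    network.load_state_dict(best_state)
    return network, history
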