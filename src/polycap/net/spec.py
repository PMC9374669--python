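"""Validated architecture descriptions for the onboard grid detector.

The canonical 15-layer network maps a 240x240x3 frame to a 4x4x15 grid
using one standard convolution at each end and 13 depthwise-separable
blocks in between.  Spatial sizes follow "same" padding with ceiling
division on stride 2 (so 15 -> 8 -> 4).  Two rows of the reference filter
table list pointwise kernel counts that contradict the printed output
channel counts; the output-size column is treated as authoritative (the
only resolution that yields a consistent channel chain and a parameter
total rounding to 3.2M), so the affected pointwise kernels are narrowed
to match.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "FeatureMap",
    "SpecError",
    "canonical_spec",
    "canonical_config_path",
    "compact_spec",
    "infer_shapes",
    "count_spec_parameters",
    "spec_from_yaml",
]

INPUT_SIZE = (240, 240, 3)
OUTPUT_SIZE = (4, 4, 15)


class SpecError(ValueError):
    """Raised when an architecture description violates its invariants."""


@dataclass(frozen=True)
class LayerSpec:
    """One weight layer: either a standard conv or a depthwise-separable block.

    Kernel shapes are ``(w_k, h_k, c_k, n_k)``; a depthwise kernel has
    ``n_k = 1`` (one filter per input channel) and is followed by a 1x1
    pointwise kernel mixing channels.  ``followed_by_bn`` places a batch
    norm after every convolution in the layer; layers without batch norm
    carry a bias instead.
    """

    index: int
    kind: str  # "standard_conv" | "depthwise_separable"
    stride: int = 1
    conv_kernel: tuple[int, int, int, int] | None = None
    depthwise_kernel: tuple[int, int, int, int] | None = None
    pointwise_kernel: tuple[int, int, int, int] | None = None
    followed_by_bn: bool = True
    bias: bool = False

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise SpecError(f"layer {self.index}: stride must be 1 or 2, got {self.stride}")
        if self.kind == "standard_conv":
            if self.conv_kernel is None or self.depthwise_kernel or self.pointwise_kernel:
                raise SpecError(f"layer {self.index}: standard_conv requires conv_kernel only")
        elif self.kind == "depthwise_separable":
            if self.conv_kernel is not None or not (self.depthwise_kernel and self.pointwise_kernel):
                raise SpecError(
                    f"layer {self.index}: depthwise_separable requires depthwise + pointwise kernels"
                )
            if self.depthwise_kernel[3] != 1:
                raise SpecError(f"layer {self.index}: depthwise kernel must have n_k = 1")
            if self.pointwise_kernel[0] != 1 or self.pointwise_kernel[1] != 1:
                raise SpecError(f"layer {self.index}: pointwise kernel must be 1x1")
            if self.pointwise_kernel[2] != self.depthwise_kernel[2]:
                raise SpecError(
                    f"layer {self.index}: pointwise c_k {self.pointwise_kernel[2]} does not "
                    f"match depthwise channel count {self.depthwise_kernel[2]}"
                )
        else:
            raise SpecError(f"layer {self.index}: unknown kind {self.kind!r}")

    @property
    def in_channels(self) -> int:
        k = self.conv_kernel if self.kind == "standard_conv" else self.depthwise_kernel
        return k[2]

    @property
    def out_channels(self) -> int:
        if self.kind == "standard_conv":
            return self.conv_kernel[3]
        return self.pointwise_kernel[3]

    def parameter_count(self, include_bn: bool = True) -> int:
        """Trainable scalars: kernel weights (+ bias, + 2 per BN channel)."""
        total = 0
        if self.kind == "standard_conv":
            w, h, c, n = self.conv_kernel
            total += w * h * c * n
            if include_bn and self.followed_by_bn:
                total += 2 * n
        else:
            dw, dh, dc, _ = self.depthwise_kernel
            total += dw * dh * dc
            _, _, pc, pn = self.pointwise_kernel
            total += pc * pn
            if include_bn and self.followed_by_bn:
                total += 2 * dc + 2 * pn
        if self.bias:
            total += self.out_channels
        return total

    def to_dict(self) -> dict:
        d = {"index": self.index, "kind": self.kind, "stride": self.stride,
             "followed_by_bn": self.followed_by_bn, "bias": self.bias}
        for key in ("conv_kernel", "depthwise_kernel", "pointwise_kernel"):
            v = getattr(self, key)
            if v is not None:
                d[key] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        kw = dict(d)
        for key in ("conv_kernel", "depthwise_kernel", "pointwise_kernel"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass(frozen=True)
class NetworkSpec:
    """An ordered stack of layers with fixed input geometry.

    ``activation`` is applied after each batch-normalised convolution;
    layers with ``followed_by_bn = False`` (the detection output) stay
    linear.  Padding is always "same" with ceiling division under stride 2.
    """

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = INPUT_SIZE
    activation: str = "relu6"
    padding_mode: str = "same_ceil"

    def __post_init__(self) -> None:
        if self.padding_mode != "same_ceil":
            raise SpecError(f"unsupported padding mode {self.padding_mode!r}")
        infer_shapes(self)  # raises on inconsistent channel chaining

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return infer_shapes(self)[-1]

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "activation": self.activation,
            "padding_mode": self.padding_mode,
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            layers=tuple(LayerSpec.from_dict(l) for l in d["layers"]),
            input_shape=tuple(d.get("input_shape", INPUT_SIZE)),
            activation=d.get("activation", "relu6"),
            padding_mode=d.get("padding_mode", "same_ceil"),
        )

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class FeatureMap:
    """A ``height x width x channels`` activation tensor."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"feature map must be 3-D, got shape {self.values.shape}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def infer_shapes(spec: NetworkSpec) -> list[tuple[int, int, int]]:
    """Per-layer output sizes ``(w_f, h_f, c_f)`` under same-ceil padding."""
    w, h, c = spec.input_shape
    shapes: list[tuple[int, int, int]] = []
    for layer in spec.layers:
        if layer.in_channels != c:
            raise SpecError(
                f"layer {layer.index}: expects {layer.in_channels} input channels "
                f"but preceding output has {c}"
            )
        w = math.ceil(w / layer.stride)
        h = math.ceil(h / layer.stride)
        if w < 1 or h < 1:
            raise SpecError(f"layer {layer.index}: non-positive spatial size")
        c = layer.out_channels
        shapes.append((w, h, c))
    return shapes


def count_spec_parameters(spec: NetworkSpec, include_bn: bool = True) -> int:
    """Trainable scalar total implied by the spec alone (no weights needed)."""
    return sum(l.parameter_count(include_bn) for l in spec.layers)


def canonical_config_path():
    """Path of the bundled YAML file reproducing the canonical architecture."""
    from pathlib import Path

    return Path(__file__).resolve().parent.parent / "configs" / "canonical.yaml"


def spec_from_yaml(path) -> NetworkSpec:
    """Load a :class:`NetworkSpec` from a structured config file."""
    import yaml

    with open(path) as fh:
        return NetworkSpec.from_dict(yaml.safe_load(fh))


def _sep(index: int, k: int, cin: int, cout: int, stride: int) -> LayerSpec:
    return LayerSpec(
        index=index,
        kind="depthwise_separable",
        stride=stride,
        depthwise_kernel=(k, k, cin, 1),
        pointwise_kernel=(1, 1, cin, cout),
    )


def canonical_spec() -> NetworkSpec:
    """The reference 15-layer architecture (output-size column authoritative)."""
    layers = [
        LayerSpec(index=1, kind="standard_conv", stride=2, conv_kernel=(3, 3, 3, 32)),
        _sep(2, 3, 32, 64, 1),
        _sep(3, 3, 64, 128, 2),
        _sep(4, 3, 128, 128, 1),   # printed pointwise n_k=256 conflicts with 60x60x128 output
        _sep(5, 3, 128, 256, 2),
        _sep(6, 3, 256, 256, 1),
        _sep(7, 3, 256, 512, 2),
        *[_sep(i, 3, 512, 512, 1) for i in range(8, 13)],
        _sep(13, 3, 512, 1024, 2),
        _sep(14, 3, 1024, 1024, 2),
        LayerSpec(index=15, kind="standard_conv", stride=1,
                  conv_kernel=(1, 1, 1024, 15), followed_by_bn=False, bias=True),
    ]
    return NetworkSpec(layers=tuple(layers), input_shape=INPUT_SIZE)


def compact_spec(input_size: int = 64, widths: tuple[int, ...] = (16, 32, 48, 64, 96),
                 grid: int = 4, out_channels: int = 15) -> NetworkSpec:
    """A narrow sibling of the canonical network for desk-scale experiments.

    Same building blocks and padding rules, reduced input resolution and
    channel widths, same ``grid x grid x 15`` detection output.  The stride
    schedule is derived from ``input_size / grid`` (must be a power of two).
    """
    factor = input_size // grid
    if factor * grid != input_size or factor & (factor - 1):
        raise SpecError("input_size / grid must be a power of two")
    n_stride2 = factor.bit_length() - 1
    layers: list[LayerSpec] = [
        LayerSpec(index=1, kind="standard_conv", stride=2, conv_kernel=(3, 3, 3, widths[0]))
    ]
    strides_left = n_stride2 - 1
    prev = widths[0]
    for i, width in enumerate(widths[1:], start=2):
        stride = 2 if strides_left > 0 else 1
        # keep one stride-1 mixing block before the last reduction when possible
        if strides_left > 0 and len(widths) - i < strides_left:
            stride = 2
        elif strides_left > 0 and i % 2 == 0:
            stride = 2
        else:
            stride = 1
        if stride == 2:
            strides_left -= 1
        layers.append(_sep(i, 3, prev, width, stride))
        prev = width
    while strides_left > 0:
        layers.append(_sep(len(layers) + 1, 3, prev, prev, 2))
        strides_left -= 1
    layers.append(LayerSpec(index=len(layers) + 1, kind="standard_conv", stride=1,
                            conv_kernel=(1, 1, prev, out_channels),
                            followed_by_bn=False, bias=True))
    return NetworkSpec(layers=tuple(layers), input_shape=(input_size, input_size, 3))
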