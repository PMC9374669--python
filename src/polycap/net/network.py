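"""Network assembly, inference, parameter accounting and checkpoints."""

from __future__ import annotations

import json

import numpy as np

from .layers import BatchNorm, Conv2D, DepthwiseConv2D, ReLU6, truncated_normal
from .spec import FeatureMap, NetworkSpec, SpecError, infer_shapes

__all__ = [
    "Network",
    "build_network",
    "forward",
    "count_parameters",
    "int8_footprint",
    "save_checkpoint",
    "load_checkpoint",
]

_ACTIVATIONS = {"relu6": ReLU6}


class Network:
    """An ordered stack of ops built from a :class:`NetworkSpec`.

    The activation from the spec follows every batch-normalised
    convolution; layers without batch norm (the detection output) stay
    linear.
    """

    def __init__(self, spec: NetworkSpec, ops: list, version: str = "v0"):
        self.spec = spec
        self.ops = ops
        self.version = version
        self._training_cache_live = False

    # -- inference -----------------------------------------------------

    def forward_batch(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        expected = self.spec.input_shape
        if x.ndim != 4 or x.shape[1:] != (expected[1], expected[0], expected[2]):
            raise ValueError(
                f"expected batch of shape (N, {expected[1]}, {expected[0]}, {expected[2]}), "
                f"got {x.shape}"
            )
        for op in self.ops:
            x = op.forward(x, training=training)
        self._training_cache_live = training
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if not self._training_cache_live:
            raise RuntimeError("backward requires a preceding forward(training=True)")
        for op in reversed(self.ops):
            dy = op.backward(dy)
        return dy

    # -- parameters ----------------------------------------------------

    def parameters(self) -> list[tuple[str, object, str]]:
        """Flat list of (op_name, op, param_key) for every trainable array."""
        out = []
        for idx, op in enumerate(self.ops):
            for key in op.parameters():
                out.append((f"op{idx:03d}.{key}", op, key))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: getattr(op, key) for name, op, key in self.parameters()}
        for idx, op in enumerate(self.ops):
            if isinstance(op, BatchNorm):
                state[f"op{idx:03d}.running_mean"] = op.running_mean
                state[f"op{idx:03d}.running_var"] = op.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, op, key in self.parameters():
            arr = np.asarray(state[name])
            if arr.shape != getattr(op, key).shape:
                raise ValueError(f"shape mismatch for {name}")
            setattr(op, key, arr.astype(getattr(op, key).dtype))
        for idx, op in enumerate(self.ops):
            if isinstance(op, BatchNorm):
                op.running_mean = np.asarray(state[f"op{idx:03d}.running_mean"], dtype=np.float64)
                op.running_var = np.asarray(state[f"op{idx:03d}.running_var"], dtype=np.float64)


def build_network(spec: NetworkSpec, rng_seed: int) -> Network:
    """Instantiate a trainable network with seeded truncated-normal weights.

    Kernels draw from a truncated normal (stddev 0.03); batch-norm scale
    starts at 1 and shift at 0; biases start at 0.  Identical spec + seed
    yields identical initial weights.
    """
    infer_shapes(spec)  # raises SpecError on inconsistent chains
    if spec.activation not in _ACTIVATIONS:
        raise SpecError(f"unknown activation {spec.activation!r}")
    act = _ACTIVATIONS[spec.activation]
    rng = np.random.default_rng(rng_seed)
    ops: list = []
    for layer in spec.layers:
        convs: list = []
        if layer.kind == "standard_conv":
            kh, kw, cin, cout = layer.conv_kernel[1], layer.conv_kernel[0], \
                layer.conv_kernel[2], layer.conv_kernel[3]
            bias = np.zeros(cout, dtype=np.float32) if layer.bias else None
            convs.append(Conv2D(truncated_normal(rng, (kh, kw, cin, cout)),
                                stride=layer.stride, bias=bias))
        else:
            dw, dh, dc, _ = layer.depthwise_kernel
            convs.append(DepthwiseConv2D(truncated_normal(rng, (dh, dw, dc)),
                                         stride=layer.stride))
            _, _, pc, pn = layer.pointwise_kernel
            pw_bias = np.zeros(pn, dtype=np.float32) if layer.bias else None
            convs.append(Conv2D(truncated_normal(rng, (1, 1, pc, pn)),
                                stride=1, bias=pw_bias))
        for conv in convs:
            ops.append(conv)
            if layer.followed_by_bn:
                channels = conv.w.shape[-1] if isinstance(conv, Conv2D) else conv.w.shape[-1]
                ops.append(BatchNorm(channels))
                ops.append(act())
    return Network(spec, ops)


def forward(network: Network, image: np.ndarray) -> FeatureMap:
    """Run one frame through the network (inference mode)."""
    image = np.asarray(image)
    w, h, c = network.spec.input_shape
    if image.shape != (h, w, c):
        raise ValueError(f"expected image of shape ({h}, {w}, {c}), got {image.shape}")
    out = network.forward_batch(image[None], training=False)
    return FeatureMap(out[0])


def count_parameters(network: Network, include_bn: bool = True) -> int:
    """Total trainable scalars; batch norm contributes 2 per channel when counted."""
    total = 0
    for op in network.ops:
        if isinstance(op, BatchNorm):
            if include_bn:
                total += op.gamma.size + op.beta.size
        else:
            total += sum(arr.size for arr in op.parameters().values())
    return total


def int8_footprint(network: Network) -> int:
    """Bytes needed to store every trainable parameter as one 8-bit integer."""
    return count_parameters(network, include_bn=True)


def save_checkpoint(network: Network, path) -> None:
    """Single-file checkpoint embedding the spec (and its hash) with the weights."""
    meta = json.dumps({"spec": network.spec.to_dict(),
                       "spec_hash": network.spec.spec_hash(),
                       "version": network.version})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **network.state_dict())


def load_checkpoint(path, spec: NetworkSpec | None = None) -> Network:
    """Rebuild a network from a checkpoint.

    If ``spec`` is given it must hash-match the stored one; loading weights
    onto a mismatched architecture is an error.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    stored_spec = NetworkSpec.from_dict(meta["spec"])
    if spec is not None and spec.spec_hash() != meta["spec_hash"]:
        raise SpecError("checkpoint spec hash does not match the requested architecture")
    network = build_network(stored_spec, rng_seed=0)
    network.load_state_dict(state)
    network.version = meta.get("version", "v0")
    return network
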