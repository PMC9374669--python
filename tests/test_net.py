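import numpy as np
import pytest

from polycap.net import (
    LayerSpec,
    NetworkSpec,
    SpecError,
    build_network,
    canonical_spec,
    compact_spec,
    count_parameters,
    count_spec_parameters,
    forward,
    infer_shapes,
    int8_footprint,
    load_checkpoint,
    save_checkpoint,
)
from polycap.net.layers import BatchNorm, Conv2D, DepthwiseConv2D

# Per-layer filter shapes transcribed by hand from the reference architecture table
# (output-size column authoritative), as an independent arithmetic oracle:
# (kind, kernel w, kernel h, in ch, out ch) -- separable rows give the
# depthwise kernel size and the pointwise in/out channels.
HAND_TABLE = [
    ("conv", 3, 3, 3, 32),
    ("sep", 3, 32, 64),
    ("sep", 3, 64, 128),
    ("sep", 3, 128, 128),
    ("sep", 3, 128, 256),
    ("sep", 3, 256, 256),
    ("sep", 3, 256, 512),
    ("sep", 3, 512, 512),
    ("sep", 3, 512, 512),
    ("sep", 3, 512, 512),
    ("sep", 3, 512, 512),
    ("sep", 3, 512, 512),
    ("sep", 3, 512, 1024),
    ("sep", 3, 1024, 1024),
    ("conv", 1, 1, 1024, 15),
]

EXPECTED_TRACE = [
    (120, 120, 32), (120, 120, 64), (60, 60, 128), (60, 60, 128),
    (30, 30, 256), (30, 30, 256), (15, 15, 512),
    (15, 15, 512), (15, 15, 512), (15, 15, 512), (15, 15, 512), (15, 15, 512),
    (8, 8, 1024), (4, 4, 1024), (4, 4, 15),
]


def hand_parameter_total(include_bn: bool) -> int:
    total = 0
    for row in HAND_TABLE:
        if row[0] == "conv":
            _, kw, kh, cin, cout = row
            total += kw * kh * cin * cout
            if include_bn and cout != 15:
                total += 2 * cout
        else:
            _, k, cin, cout = row
            total += k * k * cin + cin * cout
            if include_bn:
                total += 2 * cin + 2 * cout
    return total + 15  # final conv bias


class TestSpecValidation:
    def test_canonical_passes(self):
        spec = canonical_spec()
        assert len(spec.layers) == 15

    def test_channel_mismatch_names_layer(self):
        layers = list(canonical_spec().layers)
        bad = LayerSpec(index=3, kind="depthwise_separable", stride=2,
                        depthwise_kernel=(3, 3, 32, 1), pointwise_kernel=(1, 1, 32, 128))
        layers[2] = bad
        with pytest.raises(SpecError, match="layer 3"):
            NetworkSpec(layers=tuple(layers))

    def test_stride_must_be_1_or_2(self):
        with pytest.raises(SpecError):
            LayerSpec(index=1, kind="standard_conv", stride=3, conv_kernel=(3, 3, 3, 8))

    def test_kind_kernel_exclusivity(self):
        with pytest.raises(SpecError):
            LayerSpec(index=1, kind="standard_conv", conv_kernel=(3, 3, 3, 8),
                      depthwise_kernel=(3, 3, 3, 1))
        with pytest.raises(SpecError):
            LayerSpec(index=1, kind="depthwise_separable",
                      depthwise_kernel=(3, 3, 3, 1))

    def test_spec_roundtrip_through_dict(self):
        spec = canonical_spec()
        again = NetworkSpec.from_dict(spec.to_dict())
        assert again == spec
        assert again.spec_hash() == spec.spec_hash()


class TestShapeInference:
    def test_full_trace_matches_reference_column(self):
        assert infer_shapes(canonical_spec()) == EXPECTED_TRACE

    def test_ceiling_division_15_to_8(self):
        trace = infer_shapes(canonical_spec())
        assert trace[11][:2] == (15, 15) and trace[12][:2] == (8, 8)

    def test_stride1_keeps_spatial_size(self):
        trace = infer_shapes(canonical_spec())
        assert trace[2][:2] == trace[3][:2] == (60, 60)

    def test_final_shape(self):
        assert canonical_spec().output_shape == (4, 4, 15)


class TestParameterAccounting:
    def test_hand_total_matches_spec_total(self):
        assert count_spec_parameters(canonical_spec(), True) == hand_parameter_total(True)
        assert count_spec_parameters(canonical_spec(), False) == hand_parameter_total(False)

    def test_rounds_to_3_2_million_with_and_without_bn(self):
        spec = canonical_spec()
        for include_bn in (True, False):
            millions = count_spec_parameters(spec, include_bn) / 1e6
            assert round(millions, 1) == 3.2

    def test_network_count_equals_spec_count(self):
        net = build_network(canonical_spec(), rng_seed=0)
        assert count_parameters(net, True) == count_spec_parameters(canonical_spec(), True)
        assert count_parameters(net, False) == count_spec_parameters(canonical_spec(), False)

    def test_count_invariant_to_seed(self):
        spec = compact_spec(32)
        a = build_network(spec, rng_seed=1)
        b = build_network(spec, rng_seed=2)
        assert count_parameters(a, True) == count_parameters(b, True)

    def test_count_additive_over_layers(self):
        spec = canonical_spec()
        assert count_spec_parameters(spec, True) == sum(
            l.parameter_count(True) for l in spec.layers)

    def test_single_conv_with_bn_is_928(self):
        layer = LayerSpec(index=1, kind="standard_conv", stride=2,
                          conv_kernel=(3, 3, 3, 32))
        assert layer.parameter_count(True) == 864 + 64 == 928

    def test_footprint_is_one_byte_per_parameter(self):
        net = build_network(canonical_spec(), rng_seed=0)
        assert int8_footprint(net) == count_parameters(net, True)
        assert round(int8_footprint(net) / 1e6, 1) == 3.2

    def test_toy_layer_footprint(self):
        spec = NetworkSpec(
            layers=(LayerSpec(index=1, kind="standard_conv", stride=2,
                              conv_kernel=(3, 3, 3, 32)),),
            input_shape=(8, 8, 3))
        net = build_network(spec, rng_seed=0)
        assert int8_footprint(net) == 928

    @pytest.mark.parametrize("layer", [l for l in canonical_spec().layers
                                       if l.kind == "depthwise_separable"])
    def test_separable_cheaper_than_standard_by_up_to_k_squared(self, layer):
        k = layer.depthwise_kernel[0]
        cin, cout = layer.depthwise_kernel[2], layer.pointwise_kernel[3]
        standard = k * k * cin * cout
        separable = k * k * cin + cin * cout
        assert separable < standard
        ratio = standard / separable
        closed_form = k * k * cout / (k * k + cout)
        assert ratio == pytest.approx(closed_form)
        assert ratio < k * k


class TestBuildAndForward:
    def test_seeded_build_reproducible(self):
        spec = compact_spec(32)
        a = build_network(spec, rng_seed=5)
        b = build_network(spec, rng_seed=5)
        for (_, opa, ka), (_, opb, kb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(getattr(opa, ka), getattr(opb, kb))

    def test_different_seed_different_weights(self):
        spec = compact_spec(32)
        a = build_network(spec, rng_seed=5)
        b = build_network(spec, rng_seed=6)
        diffs = [not np.array_equal(getattr(opa, ka), getattr(opb, kb))
                 for (_, opa, ka), (_, opb, kb) in zip(a.parameters(), b.parameters())
                 if getattr(opa, ka).size > 2]
        assert any(diffs)

    def test_forward_output_shape(self):
        net = build_network(canonical_spec(), rng_seed=0)
        img = np.random.default_rng(0).random((240, 240, 3))
        fm = forward(net, img)
        assert fm.shape == (4, 4, 15)

    def test_wrong_input_shape_raises(self):
        net = build_network(compact_spec(32), rng_seed=0)
        with pytest.raises(ValueError, match="shape"):
            forward(net, np.zeros((16, 16, 3)))

    def test_zero_weights_propagate_zero(self):
        net = build_network(compact_spec(32), rng_seed=0)
        for _, op, key in net.parameters():
            if key in ("w", "b", "beta"):
                setattr(op, key, np.zeros_like(getattr(op, key)))
        out = forward(net, np.random.default_rng(1).random((32, 32, 3)))
        np.testing.assert_allclose(out.values, 0.0)

    def test_forward_deterministic(self):
        net = build_network(compact_spec(32), rng_seed=3)
        img = np.random.default_rng(2).random((32, 32, 3))
        np.testing.assert_array_equal(forward(net, img).values,
                                      forward(net, img).values)


class TestGradients:
    """Backward passes against central finite differences (float64)."""

    @staticmethod
    def _num_grad(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = x[i]
            x[i] = old + eps
            fp = f()
            x[i] = old - eps
            fm = f()
            x[i] = old
            g[i] = (fp - fm) / (2 * eps)
        return g

    def _check(self, layer, x, keys):
        rng = np.random.default_rng(0)
        dy = rng.standard_normal(layer.forward(x, training=True).shape)

        def loss():
            return float((layer.forward(x, training=True) * dy).sum())

        layer.forward(x, training=True)
        dx = layer.backward(dy)
        np.testing.assert_allclose(dx, self._num_grad(loss, x), atol=1e-6)
        for key in keys:
            np.testing.assert_allclose(layer.grads[key],
                                       self._num_grad(loss, getattr(layer, key)),
                                       atol=1e-6)

    def test_conv2d(self):
        rng = np.random.default_rng(1)
        layer = Conv2D(rng.standard_normal((3, 3, 3, 4)), stride=2,
                       bias=np.zeros(4))
        layer.w = layer.w.astype(np.float64)
        layer.b = layer.b.astype(np.float64)
        self._check(layer, rng.standard_normal((2, 7, 7, 3)), ["w", "b"])

    def test_depthwise(self):
        rng = np.random.default_rng(2)
        layer = DepthwiseConv2D(rng.standard_normal((3, 3, 3)), stride=2)
        layer.w = layer.w.astype(np.float64)
        self._check(layer, rng.standard_normal((2, 7, 7, 3)), ["w"])

    def test_batchnorm(self):
        rng = np.random.default_rng(3)
        layer = BatchNorm(3)
        layer.gamma = layer.gamma.astype(np.float64) + 0.3
        layer.beta = layer.beta.astype(np.float64) - 0.1
        self._check(layer, rng.standard_normal((2, 5, 5, 3)), ["gamma", "beta"])


class TestCheckpoints:
    def test_roundtrip(self, tmp_path):
        net = build_network(compact_spec(32), rng_seed=4)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        again = load_checkpoint(path, spec=compact_spec(32))
        img = np.random.default_rng(0).random((32, 32, 3))
        np.testing.assert_array_equal(forward(net, img).values,
                                      forward(again, img).values)

    def test_mismatched_spec_rejected(self, tmp_path):
        net = build_network(compact_spec(32), rng_seed=4)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        with pytest.raises(SpecError, match="hash"):
            load_checkpoint(path, spec=compact_spec(64))
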