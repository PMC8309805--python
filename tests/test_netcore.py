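"""Declarative architectures, shape traces, and the separable-conv primitive."""

import numpy as np
import pytest

from mammocad import (
    LayerSpec,
    NetworkSpec,
    build_dcnn,
    build_fc_dscnn,
    conv_stage_param_count,
    depthwise_separable_conv,
    shape_trace,
)
from mammocad.netcore import conv2d


def sepconv_oracle(x, dk, pk):
    """Nested-loop two-stage reference: depthwise then pointwise."""
    h, w, c = x.shape
    kh, kw, _ = dk.shape
    f = pk.shape[1]
    xp = np.pad(x, [(kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)])
    out = np.zeros((h, w, f))
    for i in range(h):
        for j in range(w):
            for fo in range(f):
                acc = 0.0
                for ci in range(c):
                    d = 0.0
                    for a in range(kh):
                        for b in range(kw):
                            d += xp[i + a, j + b, ci] * dk[a, b, ci]
                    acc += d * pk[ci, fo]
                out[i, j, fo] = acc
    return out


class TestSeparableConv:
    def test_zero_input_gives_zero_output(self):
        out = depthwise_separable_conv(
            np.zeros((5, 5, 2)), np.ones((3, 3, 2)), np.ones((2, 3))
        )
        np.testing.assert_array_equal(out, 0.0)

    def test_delta_depthwise_with_channel_sum_pointwise(self, rng):
        x = rng.random((4, 6, 3))
        dk = np.zeros((3, 3, 3))
        dk[1, 1, :] = 1.0  # identity depthwise
        pk = np.ones((3, 1))  # channel sum pointwise
        out = depthwise_separable_conv(x, dk, pk)
        np.testing.assert_allclose(out[:, :, 0], x.sum(axis=2), atol=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.normal(size=(6, 6, 3))
        dk = rng.normal(size=(3, 3, 3))
        pk = rng.normal(size=(3, 4))
        out = depthwise_separable_conv(x, dk, pk)
        assert np.abs(out - sepconv_oracle(x, dk, pk)).max() < 1e-6

    def test_stride_subsamples(self, rng):
        x = rng.normal(size=(6, 8, 2))
        dk = rng.normal(size=(3, 3, 2))
        pk = rng.normal(size=(2, 3))
        full = depthwise_separable_conv(x, dk, pk)
        strided = depthwise_separable_conv(x, dk, pk, stride=(2, 2))
        np.testing.assert_array_equal(strided, full[::2, ::2])

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            depthwise_separable_conv(
                rng.normal(size=(4, 4, 2)),
                rng.normal(size=(3, 3, 3)),
                rng.normal(size=(3, 2)),
            )

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            depthwise_separable_conv(
                rng.normal(size=(4, 4, 2)),
                rng.normal(size=(2, 2, 2)),
                rng.normal(size=(2, 2)),
            )

    def test_conv2d_matches_nested_loop(self, rng):
        x = rng.normal(size=(5, 5, 2))
        k = rng.normal(size=(3, 3, 2, 3))
        out = conv2d(x, k)
        xp = np.pad(x, [(1, 1), (1, 1), (0, 0)])
        ref = np.zeros((5, 5, 3))
        for i in range(5):
            for j in range(5):
                for f in range(3):
                    ref[i, j, f] = (xp[i : i + 3, j : j + 3] * k[:, :, :, f]).sum()
        assert np.abs(out - ref).max() < 1e-6


# the published layer-by-layer output shapes of the full-size networks
FULL_SIZE_TRACE = [
    (240, 320, 32), (240, 320, 32), (120, 160, 32),
    (120, 160, 64), (120, 160, 64), (120, 160, 64), (120, 160, 64), (60, 80, 64),
    (60, 80, 128), (60, 80, 128), (60, 80, 128), (60, 80, 128),
    (60, 80, 128), (60, 80, 128), (30, 40, 128),
    (153600,), (153600,), (256,), (2,),
]


class TestArchitectures:
    @pytest.mark.parametrize("builder", [build_fc_dscnn, build_dcnn])
    def test_full_size_shape_trace(self, builder):
        shapes = [s for _, s in shape_trace(builder((240, 320, 3)))]
        assert shapes == FULL_SIZE_TRACE

    def test_scaled_variant_flatten_length(self):
        shapes = [s for _, s in shape_trace(build_fc_dscnn((24, 32, 3)))]
        assert (1536,) in shapes
        assert shapes[-1] == (2,)

    @pytest.mark.parametrize("builder", [build_fc_dscnn, build_dcnn])
    def test_trace_row_count_covers_every_layer(self, builder):
        spec = builder()
        assert len(shape_trace(spec)) == len(spec.layers) == 19

    def test_separable_conv_stage_is_smaller(self):
        sep = conv_stage_param_count(build_fc_dscnn())
        std = conv_stage_param_count(build_dcnn())
        assert sep < std

    def test_conv_stage_count_matches_instantiated_model(self):
        from mammocad.nn import Conv2D, SeparableConv2D, build_model

        for builder in (build_fc_dscnn, build_dcnn):
            spec = builder((24, 32, 3))
            model = build_model(spec, seed=0)
            actual = sum(
                sum(p.size for p in layer.params.values())
                for layer in model.layers
                if isinstance(layer, (SeparableConv2D, Conv2D))
            )
            assert actual == conv_stage_param_count(spec)

    def test_inconsistent_spec_names_bad_layer(self):
        spec = NetworkSpec(
            "bad",
            (8, 8, 3),
            (
                LayerSpec("flatten"),
                LayerSpec("separable_conv", n_filters=4, kernel=(3, 3)),
                LayerSpec("softmax", units=2),
            ),
        )
        with pytest.raises(ValueError, match="layer 1"):
            shape_trace(spec)


class TestSerialization:
    @pytest.mark.parametrize("builder", [build_fc_dscnn, build_dcnn])
    def test_json_round_trip_is_lossless(self, builder):
        spec = builder()
        assert NetworkSpec.from_json(spec.to_json()) == spec

    def test_file_round_trip(self, tmp_path):
        spec = build_fc_dscnn((24, 32, 3))
        spec.save(tmp_path / "net.json")
        assert NetworkSpec.load(tmp_path / "net.json") == spec


class TestLayerSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "warp"},
            {"kind": "conv2d"},  # missing filters/kernel
            {"kind": "dropout", "rate": 1.5},
            {"kind": "dense"},
            {"kind": "separable_conv", "n_filters": 8, "kernel": (0, 3)},
        ],
    )
    def test_invalid_layers_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LayerSpec(**kwargs)

    def test_network_must_end_in_softmax(self):
        with pytest.raises(ValueError):
            NetworkSpec("x", (8, 8, 3), (LayerSpec("flatten"),))
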