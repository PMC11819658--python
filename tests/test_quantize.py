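"""FP16 cast/forward contracts and affine quantization arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hsifm as h
from hsifm._nn import Dense
from hsifm.quantize import round_fp16


class TestFp16Cast:
    def test_exactly_representable_value_unchanged(self):
        assert round_fp16(np.array([1.0]))[0] == 1.0

    def test_round_to_nearest_even_matches_binary16_oracle(self):
        # independent oracle: numpy's native IEEE binary16 conversion
        assert round_fp16(np.array([0.1]))[0] == 0.0999755859375
        vals = np.random.default_rng(0).normal(0, 3, 1000).astype(np.float32)
        np.testing.assert_array_equal(
            round_fp16(vals), vals.astype(np.float16).astype(np.float32)
        )

    def test_saturates_at_half_precision_max(self):
        assert round_fp16(np.array([70000.0]))[0] == 65504.0
        assert round_fp16(np.array([-70000.0]))[0] == -65504.0

    def test_cast_tags_and_preserves_counts(self, tiny_model):
        q = h.cast_fp16(tiny_model)
        assert q.precision == "fp16"
        assert q.parameter_count(True) == tiny_model.parameter_count(True)
        assert q.mac_count() == tiny_model.mac_count()

    def test_cast_is_idempotent_and_weights_representable(self, tiny_model, rng):
        q = h.cast_fp16(tiny_model)
        for p in q.net.params():
            w32 = p.value.astype(np.float32)
            np.testing.assert_array_equal(w32, round_fp16(w32))
        batch = rng.random((20, 96)).astype(np.float32)
        with pytest.warns(UserWarning):
            q2 = h.cast_fp16(q)
        np.testing.assert_array_equal(
            h.forward_fp16(q, batch), h.forward_fp16(q2, batch)
        )

    def test_forward_fp16_requires_fp16_model(self, tiny_model, rng):
        with pytest.raises(ValueError):
            h.forward_fp16(tiny_model, rng.random((4, 96)))


class TestFp16Forward:
    def test_exact_on_representable_single_linear_layer(self):
        # integer weights and inputs: no rounding anywhere, fp16 emulation
        # must reproduce the fp32 result bit for bit
        dense = Dense(8, 3, rng=np.random.default_rng(0))
        dense.w.value = np.arange(24, dtype=np.float32).reshape(3, 8) - 12
        dense.b.value = np.array([1.0, -2.0, 3.0], dtype=np.float32)
        x = np.arange(16, dtype=np.float32).reshape(2, 8)
        y32 = dense.forward(x)
        y16 = round_fp16(dense.forward(round_fp16(x)))
        np.testing.assert_array_equal(y16, y32)

    def test_probability_drift_bounded_on_fixture(self, tiny_model, rng):
        batch = rng.random((500, 96)).astype(np.float32)
        p32 = h.score_spectra(tiny_model, batch)
        p16 = h.forward_fp16(h.cast_fp16(tiny_model), batch)
        assert np.abs(p32 - p16).max() <= 1e-2
        assert p16.min() >= 0.0 and p16.max() <= 1.0


class TestSizeReport:
    def test_printed_model_sizes(self):
        rep = h.model_size(6359)
        assert rep.kb_fp32 == 24.8
        assert rep.kb_fp16 == 12.4
        assert rep.reduction_percent == 50.0

    def test_zero_parameters(self):
        rep = h.model_size(0)
        assert rep.bytes_fp32 == 0 and rep.kb_fp16 == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            h.model_size(-1)


class TestAffine:
    def test_identity_grid(self):
        qp = h.affine_quant_params(0.0, 255.0, nbits=8)
        assert qp.S == 1.0 and qp.Z == 0

    def test_symmetric_unit_range(self):
        qp = h.affine_quant_params(-1.0, 1.0, nbits=8)
        assert qp.S == pytest.approx(2 / 255)
        assert qp.Z == 128

    def test_per_channel_distinct_scales(self, rng):
        qp = h.affine_quant_params(
            [0.0, -1.0], [1.0, 1.0], nbits=8, granularity="per_channel"
        )
        assert qp.S[0] != qp.S[1]
        t = rng.random((2, 10))
        q = h.affine_quantize(t, qp)
        assert q.shape == t.shape

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            h.affine_quant_params(0.3, 0.3)

    @settings(max_examples=40, deadline=None)
    @given(
        rmin=st.floats(-10, 0), rmax=st.floats(0.1, 20),
        nbits=st.sampled_from([4, 8]), seed=st.integers(0, 2**16),
    )
    def test_round_trip_error_within_half_scale(self, rmin, rmax, nbits, seed):
        # ranges spanning zero: the regime where the zero point is on-grid
        # (post-ReLU activation and symmetric weight ranges both qualify)
        qp = h.affine_quant_params(rmin, rmax, nbits=nbits)
        x = np.random.default_rng(seed).uniform(rmin, rmax, 200)
        xhat = h.affine_dequantize(h.affine_quantize(x, qp), qp)
        assert np.abs(x - xhat).max() <= qp.S / 2 + 1e-12

    def test_group_granularity(self, rng):
        qp = h.affine_quant_params(
            [0.0, -2.0], [1.0, 2.0], nbits=8, granularity="group", group_size=2
        )
        t = rng.uniform(-1, 1, (4, 5))
        xhat = h.affine_dequantize(h.affine_quantize(t, qp), qp)
        assert xhat.shape == t.shape
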