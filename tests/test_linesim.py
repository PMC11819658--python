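"""Latency protocol, throughput/unit arithmetic and line-speed feasibility."""

import numpy as np
import pytest

import hsifm as h
from hsifm.linesim import CameraSpec


class _CountingEngine:
    def __init__(self):
        self.calls = 0

    def __call__(self, batch):
        self.calls += 1


class _FakeClock:
    """Advances a fixed interval on every call."""

    def __init__(self, step_s):
        self.t, self.step = 0.0, step_s

    def __call__(self):
        self.t += self.step
        return self.t


class TestLatencyProtocol:
    def test_warmups_plus_reps_invocations(self):
        engine = _CountingEngine()
        stats = h.measure_latency(engine, None, warmup=5, reps=10, clock=_FakeClock(1e-3))
        assert engine.calls == 15
        assert stats.warmup_runs == 5 and stats.reps == 10

    def test_fake_clock_gives_exact_mean_and_zero_sd(self):
        stats = h.measure_latency(
            _CountingEngine(), None, warmup=5, reps=10, clock=_FakeClock(0.005)
        )
        assert stats.mean_s == pytest.approx(0.005)
        assert stats.sd_s == pytest.approx(0.0, abs=1e-12)

    def test_single_rep_sd_zero_by_convention(self):
        stats = h.measure_latency(
            _CountingEngine(), None, warmup=0, reps=1, clock=_FakeClock(0.001)
        )
        assert stats.sd_s == 0.0

    def test_engine_failure_annotated_with_run_index(self):
        def broken(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="warm-up run 0"):
            h.measure_latency(broken, None)

    def test_reps_must_be_positive(self):
        with pytest.raises(ValueError):
            h.measure_latency(_CountingEngine(), None, reps=0)


class TestThroughput:
    def test_unit_definition(self):
        assert h.throughput(1e6, 1.0) == 1.0
        assert h.throughput(0, 1.0) == 0.0
        assert h.throughput(2e6, 0.5) == 4.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            h.throughput(1e6, 0.0)

    def test_pixel_byte_consistency_for_96_band_spectra(self):
        pixels, seconds = 1000, 2.0
        mb_s = h.throughput(pixels * 384, seconds)
        assert mb_s * 1e6 / 384 == pytest.approx(pixels / seconds)


class TestHypercubeGeometry:
    def test_preset_spectra_counts(self):
        assert h.hypercube_pixels(h.swir_camera()) == 256_000
        assert h.hypercube_pixels(h.nir_camera()) == 107_520

    def test_degenerate_one_pixel_camera(self):
        cam = CameraSpec(
            name="tiny", spatial_pixels=1, native_bands=96,
            wavelength_range_nm=(1000, 1700), max_line_rate=1.0,
            res_cross_mm=0.4, res_along_mm=0.4, image_width_px=1, image_lines=1,
        )
        assert h.hypercube_pixels(cam) == 1

    def test_configured_width_cannot_exceed_detector(self):
        with pytest.raises(ValueError):
            CameraSpec(
                name="bad", spatial_pixels=320, native_bands=96,
                wavelength_range_nm=(1000, 1700), max_line_rate=45,
                res_cross_mm=0.4, res_along_mm=0.3, image_width_px=640,
                image_lines=800,
            )


class TestHypercubeRate:
    def test_exact_and_floored(self):
        exact, whole = h.hypercube_rate(512_000, h.swir_camera())
        assert exact == 2.0 and whole == 2
        exact, whole = h.hypercube_rate(8.4672e6, h.nir_camera())
        assert exact == pytest.approx(78.75)
        assert whole == 78

    def test_one_cube_per_second(self):
        cam = h.nir_camera()
        exact, whole = h.hypercube_rate(h.hypercube_pixels(cam), cam)
        assert exact == 1.0 and whole == 1

    def test_rate_times_pixels_closes_dimensionally(self):
        cam = h.swir_camera()
        exact, _ = h.hypercube_rate(640_000, cam)
        assert exact * h.hypercube_pixels(cam) == pytest.approx(640_000)


class TestLineSpeed:
    def test_printed_conversions(self):
        assert h.required_fillet_rate(140) == 4.7
        assert h.required_fillet_rate(250) == 8.3
        assert h.required_fillet_rate(0) == 0.0

    def test_feasibility_examples_and_boundary(self):
        assert h.feasibility(9.0, 250).feasible
        assert not h.feasibility(4.0, 140).feasible
        assert h.feasibility(4.7, 140).feasible  # boundary inclusive

    def test_feasibility_monotone_in_rate(self, rng):
        verdicts = [h.feasibility(r, 140).feasible for r in np.linspace(0, 10, 50)]
        assert verdicts == sorted(verdicts)


class TestScanGeometry:
    def test_swir_perpendicular_fits(self):
        g = h.scan_geometry(228.6, 127.0, h.swir_camera(), "perpendicular")
        assert g.required_width_px == 318  # ceil(127 / 0.4)
        assert g.required_lines == 762  # ceil(228.6 / 0.3)
        assert g.fits

    def test_nir_parallel_fits(self):
        g = h.scan_geometry(228.6, 127.0, h.nir_camera(), "parallel")
        assert g.required_width_px == 572
        assert g.required_lines == 159
        assert g.fits

    def test_oversized_product_does_not_fit(self):
        g = h.scan_geometry(500.0, 300.0, h.swir_camera(), "perpendicular")
        assert not g.fits


class TestAcquisitionLimit:
    def test_optics_only_cube_rates(self):
        assert h.acquisition_limit(h.nir_camera()) == pytest.approx(670 / 168)
        assert h.acquisition_limit(h.swir_camera()) == pytest.approx(45 / 800)

    def test_line_rate_equal_to_lines_gives_one(self):
        cam = CameraSpec(
            name="unit", spatial_pixels=10, native_bands=96,
            wavelength_range_nm=(1000, 1700), max_line_rate=168.0,
            res_cross_mm=0.4, res_along_mm=0.4, image_width_px=10, image_lines=168,
        )
        assert h.acquisition_limit(cam) == 1.0
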