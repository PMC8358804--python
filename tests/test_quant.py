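"""Quantitative ICC: calibration, segmentation, morphometry, densitometry,
and immune-cell counting."""

import dataclasses

import numpy as np
import pytest

from efferentquant.quant import (
    CalibrationCurve,
    DegenerateFieldError,
    ImageFrame,
    button_density,
    count_immune_cells,
    default_calibration,
    densitometry_table,
    field_od_stats,
    fit_gray_to_od,
    normalized_od,
    sample_buttons_for_densitometry,
    segment_buttons,
)
from efferentquant.synthetic import CochleaSimConfig, simulate_cochlea_image


class TestCalibration:
    def test_linear_midpoint_and_knots(self):
        cal = fit_gray_to_od([(255.0, 0.0), (0.0, 2.0)])
        assert cal(127.5) == pytest.approx(1.0)
        assert cal(255.0) == 0.0 and cal(0.0) == 2.0

    def test_non_monotone_grays_rejected(self):
        with pytest.raises(ValueError):
            fit_gray_to_od([(100.0, 1.0), (100.0, 0.5)])
        with pytest.raises(ValueError):
            fit_gray_to_od([(50.0, 0.5), (200.0, 1.5)])  # OD rising with gray

    def test_interpolant_tracks_analytic_transmission_curve(self):
        cal = default_calibration()
        g = np.linspace(cal.gray[0], 255.0, 500)
        analytic = np.log10(255.0 / g)
        assert np.max(np.abs(cal(g) - analytic)) < 0.02

    def test_monotone_everywhere(self):
        cal = default_calibration()
        g = np.linspace(cal.gray[0], 255.0, 1000)
        assert np.all(np.diff(cal(g)) <= 1e-12)

    def test_out_of_range_clamps_with_warning(self):
        cal = fit_gray_to_od([(100.0, 1.0), (200.0, 0.2)])
        with pytest.warns(UserWarning, match="clamped"):
            assert cal(250.0) == pytest.approx(0.2)


class TestSegmentation:
    def test_blank_frame_empty(self):
        frame = ImageFrame(pixels=np.full((64, 64), 200, dtype=np.uint8))
        assert segment_buttons(frame) == []

    def test_5x5_square_is_exactly_one_um2(self):
        img = np.full((40, 40), 220, dtype=np.uint8)
        img[5:10, 5:10] = 50
        (seg,) = segment_buttons(ImageFrame(pixels=img), threshold=128)
        assert seg.pixel_count == 25
        assert seg.area_um2 == pytest.approx(1.0, abs=1e-12)

    def test_area_gate_discards_out_of_range_components(self):
        img = np.full((200, 200), 220, dtype=np.uint8)
        img[5:8, 5:8] = 50  # 9 px = 0.36 µm², below min
        img[50:150, 50:150] = 50  # 400 µm², above max
        img[20:30, 150:160] = 50  # 4 µm², in range
        segs = segment_buttons(ImageFrame(pixels=img), threshold=128)
        assert len(segs) == 1 and segs[0].area_um2 == pytest.approx(4.0)

    def test_invalid_threshold_rejected(self):
        frame = ImageFrame(pixels=np.full((8, 8), 100, dtype=np.uint8))
        with pytest.raises(ValueError):
            segment_buttons(frame, threshold=300)

    def test_simulator_ground_truth_count(self, sham_frame):
        frame, truth = sham_frame
        segs = segment_buttons(frame, threshold=150.0)
        assert len(segs) == truth.n_buttons


class TestMorphometry:
    def test_density_arithmetic(self):
        assert button_density(range(40), 20_000.0) == pytest.approx(20.0)
        assert button_density([], 5_000.0) == 0.0
        with pytest.raises(ValueError):
            button_density([], 0.0)

    def test_poisson_density_recovery(self):
        rng = np.random.default_rng(3)
        d_true = 40.0
        dens = []
        for _ in range(30):
            cfg = CochleaSimConfig(seed=int(rng.integers(2**31 - 1)))
            frame, truth = simulate_cochlea_image(cfg, 11.3)
            # density is defined over the usable (button-bearing) area
            usable = frame.area_um2 * (1 - cfg.fiber_band_fraction)
            dens.append(truth.n_buttons * 10_000.0 / usable)
        se = np.sqrt(d_true / (usable / 10_000.0) / len(dens))
        assert abs(np.mean(dens) - d_true) < 3 * se


class TestDensitometry:
    def test_uniform_field(self):
        cal = default_calibration()
        frame = ImageFrame(pixels=np.full((32, 32), 128, dtype=np.uint8))
        fs = field_od_stats(frame, cal)
        assert fs.mean_od == pytest.approx(float(cal(128.0)))
        assert fs.sd_od == 0.0

    def test_two_value_field_population_sd(self):
        cal = fit_gray_to_od([(50.0, 2.0), (200.0, 0.0)])
        px = np.full((10, 10), 200, dtype=np.uint8)
        px[:5] = 50
        fs = field_od_stats(ImageFrame(pixels=px), cal)
        assert fs.mean_od == pytest.approx(1.0)
        assert fs.sd_od == pytest.approx(1.0)  # population convention

    def test_matches_brute_force_per_pixel(self):
        rng = np.random.default_rng(4)
        px = rng.integers(30, 250, size=(40, 40)).astype(np.uint8)
        cal = default_calibration()
        fs = field_od_stats(ImageFrame(pixels=px), cal)
        ods = [float(cal(float(v))) for v in px.ravel()]
        assert fs.mean_od == pytest.approx(np.mean(ods))
        assert fs.sd_od == pytest.approx(np.std(ods))

    def test_normalized_od_anchors(self):
        from efferentquant.quant import FieldStats

        fs = FieldStats(mean_od=0.4, sd_od=0.1, n_pixels=100)
        assert normalized_od(0.4, fs) == pytest.approx(0.0)
        assert normalized_od(0.6, fs) == pytest.approx(2.0)
        with pytest.raises(DegenerateFieldError):
            normalized_od(0.5, FieldStats(mean_od=0.4, sd_od=0.0, n_pixels=100))

    def test_self_normalization_identity(self):
        rng = np.random.default_rng(5)
        px = rng.integers(30, 250, size=(64, 64)).astype(np.uint8)
        cal = default_calibration()
        frame = ImageFrame(pixels=px)
        fs = field_od_stats(frame, cal)
        z = (cal(px.astype(float)) - fs.mean_od) / fs.sd_od
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1.0) < 1e-9


class TestButtonSampling:
    def test_subset_size_and_determinism(self):
        segs = list(range(50))
        s1 = sample_buttons_for_densitometry(segs, n=30, seed=9)
        s2 = sample_buttons_for_densitometry(segs, n=30, seed=9)
        assert len(s1) == 30 == len(set(s1)) and s1 == s2
        s3 = sample_buttons_for_densitometry(segs, n=30, seed=10)
        assert s3 != s1

    def test_shortfall_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="only 20"):
            out = sample_buttons_for_densitometry(list(range(20)), n=30, seed=0)
        assert out == list(range(20))

    def test_densitometry_fills_od_fields(self, sham_frame):
        frame, _ = sham_frame
        segs = segment_buttons(frame, threshold=150.0)
        sampled, fs = densitometry_table(frame, segs, default_calibration(), n=10, seed=0)
        assert len(sampled) == 10
        for s in sampled:
            assert s.od is not None and s.norm_od is not None
            assert s.norm_od == pytest.approx((s.od - fs.mean_od) / fs.sd_od)


class TestImmuneCells:
    def test_rate_arithmetic_on_rendered_cells(self):
        cfg = CochleaSimConfig(
            macrophage_rate_per_1000um=20.0, monocyte_rate_per_1000um=20.0, seed=21
        )
        frame, truth = simulate_cochlea_image(cfg, 11.3)
        assert truth.n_macrophages > 0 and truth.n_monocytes > 0
        counts = count_immune_cells(frame, analyzed_length_um=2000.0)
        assert counts.ir_macrophages == truth.n_macrophages
        assert counts.monocytes == truth.n_monocytes
        assert counts.macrophages_per_1000um == pytest.approx(
            truth.n_macrophages * 0.5
        )

    def test_empty_frame_counts_zero(self):
        frame, _ = simulate_cochlea_image(CochleaSimConfig(seed=1), 11.3)
        counts = count_immune_cells(frame, analyzed_length_um=1000.0)
        assert counts.ir_macrophages == 0 and counts.monocytes == 0

    def test_rates_recover_generator_rates(self):
        rng = np.random.default_rng(6)
        macro = mono = 0
        t_macro = t_mono = 0
        n = 60
        for _ in range(n):
            cfg = CochleaSimConfig(
                macrophage_rate_per_1000um=8.0,
                monocyte_rate_per_1000um=6.0,
                seed=int(rng.integers(2**31 - 1)),
            )
            frame, truth = simulate_cochlea_image(cfg, 11.3)
            c = count_immune_cells(frame, analyzed_length_um=frame.pixels.shape[1] * 0.2)
            macro += c.ir_macrophages
            mono += c.monocytes
            t_macro += truth.n_macrophages
            t_mono += truth.n_monocytes
        # counted totals track rendered totals within Poisson error
        assert abs(macro - t_macro) <= 3 * np.sqrt(max(t_macro, 1))
        assert abs(mono - t_mono) <= 3 * np.sqrt(max(t_mono, 1))
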