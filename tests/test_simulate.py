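"""Synthetic-data generator contracts: MDA trajectories, spectral structure,
film artifacts, cube spatialization and dataset determinism."""

import numpy as np
import pytest

from oxispec.hypercube import (DEFAULT_WAVELENGTHS_NM, band_difference_image,
                               threshold_mask)
from oxispec.simulate import (DIP_SD_NM, MDA_LINKED_NM, FilmParams,
                              GeneratorConfig, apply_film_effect, build_cube,
                              build_gradient_cube, clean_spectrum_template,
                              expected_mda, generate_dataset,
                              measured_dip_depths, simulate_clean_spectrum,
                              simulate_mda)

WL = DEFAULT_WAVELENGTHS_NM


class TestMdaTrajectories:
    def test_blank_group_crosses_threshold_between_day3_and_day4(self):
        assert expected_mda(1, "blank") < 0.15
        assert expected_mda(3, "blank") < 0.15
        assert expected_mda(4, "blank") > 0.15
        assert expected_mda(7, "blank") > 0.15

    def test_pe_group_stays_fresh_all_week(self):
        for day in range(1, 8):
            assert expected_mda(day, "pe_packed") < 0.15
        assert expected_mda(7, "pe_packed") <= 0.13

    def test_invalid_group_raises(self, rng):
        with pytest.raises(ValueError, match="group"):
            simulate_mda(1, "vacuum", rng)

    def test_zero_noise_is_deterministic(self, rng):
        vals = {simulate_mda(5, "blank", rng, noise_sd=0.0) for _ in range(5)}
        assert vals == {expected_mda(5, "blank")}

    def test_truncated_at_zero(self):
        rng = np.random.default_rng(0)
        draws = [simulate_mda(1, "blank", rng, noise_sd=0.5) for _ in range(200)]
        assert min(draws) >= 0.0


class TestCleanSpectra:
    def test_zero_noise_equals_template(self):
        spec = simulate_clean_spectrum(0.12, 3)
        assert np.array_equal(spec, clean_spectrum_template(0.12, 3))

    def test_mda_moves_only_linked_bands(self):
        lo = clean_spectrum_template(0.1, 2)
        hi = clean_spectrum_template(0.3, 2)
        diff = np.abs(lo - hi)
        linked = np.zeros(WL.size, dtype=bool)
        for c in MDA_LINKED_NM:
            linked |= np.abs(WL - c) < 4 * DIP_SD_NM
        assert diff[linked].max() > 1e-3
        assert np.all(diff[~linked] == 0.0)

    def test_noisy_draws_stay_in_physical_band(self):
        rng = np.random.default_rng(11)
        mn, mx = 1.0, 0.0
        for _ in range(1000):
            s = simulate_clean_spectrum(rng.uniform(0, 0.31), rng.integers(1, 8),
                                        rng, noise_sd=0.003, scatter_sd=0.006,
                                        offset_sd=0.003)
            mn, mx = min(mn, s.min()), max(mx, s.max())
        assert mn >= 0.25 and mx <= 0.60

    def test_negative_mda_rejected(self):
        with pytest.raises(ValueError):
            clean_spectrum_template(-0.1)


class TestFilmEffect:
    def test_neutral_parameters_are_identity(self):
        spec = clean_spectrum_template(0.2, 4)
        film = FilmParams(attenuation=1.0, peak560_suppression=0.0,
                          ripple_amplitude=0.0, noise_sd=0.0)
        assert np.allclose(apply_film_effect(spec, film), spec, atol=1e-12)

    def test_filmed_reflectance_below_half(self):
        rng = np.random.default_rng(5)
        film = FilmParams()
        mx = max(apply_film_effect(
            clean_spectrum_template(rng.uniform(0, 0.31), rng.integers(1, 8)),
            film, rng).max() for _ in range(500))
        assert mx < 0.5

    def test_monotone_below_clean_without_ripple(self):
        film = FilmParams(ripple_amplitude=0.0, noise_sd=0.0)
        for day in range(1, 8):
            for mda in (0.0, 0.15, 0.31):
                clean = clean_spectrum_template(mda, day)
                assert np.all(apply_film_effect(clean, film) <= clean)

    def test_single_ripple_has_dominant_fft_component(self):
        rng = np.random.default_rng(3)
        film = FilmParams(ripple_amplitude=0.02, ripple_period_bands=8.0,
                          period_jitter=0.0, n_ripple=1, noise_sd=0.0)
        clean = clean_spectrum_template(0.1, 1)
        resid = apply_film_effect(clean, film, rng) - film.attenuation * (
            clean + film.peak560_suppression * 0.06
            * np.where(np.abs(WL - 560) < 4 * DIP_SD_NM,
                       np.exp(-((WL - 560) ** 2) / (2 * DIP_SD_NM**2)), 0))
        spectrum = np.abs(np.fft.rfft(resid))
        freqs = np.fft.rfftfreq(WL.size)
        assert abs(freqs[np.argmax(spectrum)] - 1 / 8) < 0.01


class TestCubes:
    def test_zero_noise_pixels_equal_input(self):
        spec = clean_spectrum_template(0.2, 2)
        cube, fg = build_cube(spec, (16, 16), noise_sd=0.0)
        assert np.allclose(cube.data[fg], spec)
        assert np.allclose(cube.data[~fg], 0.05)

    def test_roi_pipeline_recovers_constructed_foreground(self):
        spec = clean_spectrum_template(0.15, 3)
        cube, fg = build_cube(spec, (24, 24), noise_sd=0.0)
        diff = band_difference_image(cube, cube.band_nearest(810),
                                     cube.band_nearest(450))
        mask = threshold_mask(diff, threshold=0.2)
        assert mask.n_foreground == fg.sum()

    def test_mean_roi_recovers_spectrum_within_clt_bound(self):
        rng = np.random.default_rng(8)
        spec = clean_spectrum_template(0.2, 5)
        cube, fg = build_cube(spec, (24, 24), rng, noise_sd=0.005)
        assert fg.sum() >= 100
        mean = cube.data[fg].mean(axis=0)
        assert np.abs(mean - spec).max() < 0.002

    def test_too_small_cube_rejected(self):
        with pytest.raises(ValueError, match="4x4"):
            build_cube(np.zeros(125), (3, 8))

    def test_gradient_cube_orders_columns_by_mda(self):
        rng = np.random.default_rng(9)
        cube, fg, col_mda = build_gradient_cube(0.2, rng=rng, gradient=0.5,
                                                noise_sd=0.0)
        assert col_mda[0] < col_mda[-1]
        depths = measured_dip_depths(cube.data[fg])
        assert depths.shape[1] == 2


class TestDataset:
    def test_default_study_size(self, default_dataset):
        assert default_dataset.x.shape == (420, 125)
        assert (default_dataset.truth_table().groupby("group").size() == 210).all()

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_days=2, samples_per_day_per_group=4, seed=42)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(a.x, b.x)
        assert a.truth_table().equals(b.truth_table())

    def test_group_day_means_match_expectations(self, default_dataset):
        tt = default_dataset.truth_table()
        for group, sd in (("blank", 0.02), ("pe_packed", 0.015)):
            se = sd / np.sqrt(30)
            for day in range(1, 8):
                m = tt[(tt.group == group) & (tt.day == day)].mda_mg_per_100g.mean()
                assert abs(m - expected_mda(day, group)) < 4 * se

    def test_mda_signal_linearly_recoverable(self, default_dataset):
        ds = default_dataset.subset("blank")
        # noise-off: depths are exactly affine in MDA -> perfect OLS fit
        x0 = np.array([clean_spectrum_template(m, d)
                       for m, d in zip(ds.y, ds.days)])
        for x, floor in ((x0, 1.0 - 1e-10), (ds.x, 0.9)):
            depths = measured_dip_depths(x)
            design = np.column_stack([depths, np.ones(len(ds.y))])
            coef, *_ = np.linalg.lstsq(design, ds.y, rcond=None)
            resid = ds.y - design @ coef
            r2 = 1 - resid @ resid / np.sum((ds.y - ds.y.mean()) ** 2)
            assert r2 >= floor
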