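"""De-interference filters: brute-force oracles, linearity, edge policies
and effectiveness against synthetic film artifacts."""

import numpy as np
import pytest

from oxispec.filters import (FilterSpec, design_lowpass_fir, fir_filter,
                             gaussian_filter, median_filter)
from oxispec.simulate import FilmParams, apply_film_effect, clean_spectrum_template


def brute_gaussian(x, sigma, radius):
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        num = den = 0.0
        for j in range(max(0, i - radius), min(n, i + radius + 1)):
            w = np.exp(-((i - j) ** 2) / (2 * sigma**2))
            num += w * x[j]
            den += w
        out[i] = num / den
    return out


def brute_median(x, k):
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        window = [x[min(max(j, 0), n - 1)] for j in range(i - k, i + k + 1)]
        out[i] = np.median(window)
    return out


def brute_fir(x, h):
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        for k, hk in enumerate(h):
            if i - k >= 0:
                out[i] += hk * x[i - k]
    return out


class TestGaussian:
    def test_preserves_constants(self):
        assert np.allclose(gaussian_filter(np.full(50, 0.4)), 0.4, atol=1e-12)

    def test_impulse_center_weight(self):
        x = np.zeros(9)
        x[4] = 1.0
        out = gaussian_filter(x, sigma=1.0, radius=2)
        assert out[4] == pytest.approx(0.40262, abs=1e-5)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            x = rng.standard_normal(60)
            assert np.allclose(gaussian_filter(x, 2.0, 6),
                               brute_gaussian(x, 2.0, 6), atol=1e-10)

    def test_linear(self, rng):
        x, z = rng.standard_normal((2, 80))
        lhs = gaussian_filter(2.5 * x - 1.5 * z, 2.0, 6)
        rhs = 2.5 * gaussian_filter(x, 2.0, 6) - 1.5 * gaussian_filter(z, 2.0, 6)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            gaussian_filter(np.zeros(10), sigma=0.0)


class TestMedian:
    def test_spike_removed(self):
        out = median_filter(np.array([1.0, 9.0, 1.0, 1.0, 1.0]), k_half=1)
        assert np.array_equal(out, np.ones(5))

    def test_monotone_preserved_within_range(self, rng):
        x = np.sort(rng.standard_normal(40))
        out = median_filter(x, k_half=2)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= x.min() and out.max() <= x.max()

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            x = rng.standard_normal(50)
            assert np.allclose(median_filter(x, 2), brute_median(x, 2), atol=1e-12)

    def test_oversized_window_raises(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros(5), k_half=5)


class TestFir:
    def test_identity_tap(self, rng):
        x = rng.standard_normal(30)
        assert np.array_equal(fir_filter(x, [1.0]), x)

    def test_hand_convolution(self):
        out = fir_filter(np.array([2.0, 4.0, 6.0]), [0.5, 0.5])
        assert np.allclose(out, [1.0, 3.0, 5.0])

    def test_matches_bruteforce(self, rng):
        h = rng.standard_normal(7)
        for _ in range(20):
            x = rng.standard_normal(40)
            assert np.allclose(fir_filter(x, h), brute_fir(x, h), atol=1e-10)


class TestLowpassDesign:
    def test_unit_dc_gain_and_symmetry(self):
        taps = design_lowpass_fir(0.15, 21)
        assert taps.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(taps, taps[::-1], atol=1e-12)

    def test_constant_preserved(self):
        taps = design_lowpass_fir(0.15, 21)
        out = fir_filter(np.full(100, 0.37), taps)
        assert np.allclose(out[30:], 0.37, atol=1e-8)  # after transient

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            design_lowpass_fir(0.6, 21)
        with pytest.raises(ValueError):
            design_lowpass_fir(0.15, 20)


class TestDeinterference:
    def test_every_filter_reduces_film_residual_variance(self):
        # residuals measured on central bands; the linear-phase FIR output is
        # advanced by its group delay so the comparison is shift-fair
        rng = np.random.default_rng(21)
        film = FilmParams()
        core = slice(15, 110)
        delays = {"gaussian": 0, "median": 0, "fir": 10}
        reductions = {}
        for kind in ("gaussian", "median", "fir"):
            spec_filter = FilterSpec(kind)
            before = after = 0.0
            for _ in range(40):
                clean = clean_spectrum_template(rng.uniform(0, 0.31),
                                                rng.integers(1, 8))
                target = film.attenuation * clean
                filmed = apply_film_effect(clean, film, rng)
                filtered = np.roll(spec_filter.apply(filmed), -delays[kind])
                before += np.var((filmed - target)[core])
                after += np.var((filtered - target)[core])
            assert after < before
            reductions[kind] = before - after
        assert max(reductions, key=reductions.get) == "gaussian"
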