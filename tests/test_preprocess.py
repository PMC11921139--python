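"""Spectral pretreatments: definitional checks, closed-form oracles,
idempotence and the calibration-only fitting boundary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oxispec.preprocess import (MSC, OSC, RowDegeneracyError, baseline, detrend,
                                normalize, savgol, snv)

finite_rows = arrays(np.float64, (3, 20),
                     elements=st.floats(-10, 10, allow_nan=False))


class TestSNV:
    def test_hand_example(self):
        assert np.allclose(snv([[1.0, 2.0, 3.0]]), [[-1.0, 0.0, 1.0]])

    def test_constant_row_rejected(self):
        with pytest.raises(RowDegeneracyError, match="1"):
            snv([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])

    def test_rows_standardized(self, rng):
        out = snv(rng.uniform(0, 1, (10, 50)))
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(finite_rows)
    def test_idempotent(self, x):
        if np.any(x.std(axis=1, ddof=1) < 1e-3):  # skip ill-conditioned rows
            return
        once = snv(x)
        assert np.allclose(snv(once), once, atol=1e-10)


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.uniform(0.3, 0.5, 40)
        x = np.vstack([ref, 2 * ref + 0.1])
        out = MSC(reference=ref).fit(x).transform(x)
        assert np.allclose(out[0], ref, atol=1e-10)
        assert np.allclose(out[1], ref, atol=1e-10)

    def test_coefficients_match_simple_regression(self, rng):
        x = rng.uniform(0.2, 0.6, (6, 30))
        m = MSC().fit(x)
        ref = m.reference_
        out = m.transform(x)
        for i, row in enumerate(x):
            b, a = np.polyfit(ref, row, 1)
            assert np.allclose(out[i], (row - a) / b, atol=1e-10)

    def test_fitting_state_ignores_new_rows(self, rng):
        cal = rng.uniform(0.2, 0.6, (8, 30))
        m = MSC().fit(cal)
        ref_before = m.reference_.copy()
        m.transform(rng.uniform(0, 5, (4, 30)))
        assert np.array_equal(m.reference_, ref_before)


class TestRowLocalTreatments:
    def test_normalize_hand_example(self):
        assert np.allclose(normalize([[2.0, 4.0, 6.0]]), [[0.0, 0.5, 1.0]])

    def test_normalize_flat_row_rejected(self):
        with pytest.raises(RowDegeneracyError):
            normalize([[1.0, 1.0, 1.0]])

    def test_baseline_offset_invariance_and_idempotence(self, rng):
        x = rng.uniform(0, 1, (5, 40))
        assert np.allclose(baseline(x + 0.3), baseline(x), atol=1e-12)
        assert np.allclose(baseline(baseline(x)), baseline(x), atol=1e-12)

    def test_detrend_annihilates_quadratic(self):
        t = np.arange(50, dtype=float)
        row = 0.3 + 0.02 * t - 0.001 * t**2
        assert np.abs(detrend(row[None, :], order=2)).max() < 1e-10


class TestSavGol:
    def test_polynomial_passthrough(self):
        t = np.arange(60, dtype=float)
        row = 1.0 + 0.5 * t + 0.01 * t**2
        out = savgol(row[None, :], window=11, polyorder=2)
        assert np.abs(out - row).max() < 1e-9

    def test_first_derivative_of_line_is_slope(self):
        row = 0.2 + 0.03 * np.arange(60)
        out = savgol(row[None, :], window=11, polyorder=2, deriv=1)
        assert np.allclose(out, 0.03, atol=1e-10)

    def test_impulse_kernel_symmetric_unit_sum(self):
        row = np.zeros(41)
        row[20] = 1.0
        out = savgol(row[None, :], window=11, polyorder=2)[0]
        kernel = out[15:26]
        assert np.allclose(kernel, kernel[::-1], atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            savgol(np.zeros((1, 20)), window=10)
        with pytest.raises(ValueError):
            savgol(np.zeros((1, 20)), window=3, polyorder=4)


class TestOSC:
    def _data(self, rng, n=40, b=30):
        x = rng.standard_normal((n, b))
        y = x[:, 0] + 0.1 * rng.standard_normal(n)
        return x, y

    def test_removed_scores_orthogonal_to_response(self, rng):
        x, y = self._data(rng)
        m = OSC(n_components=2).fit(x, y)
        yc = y - y.mean()
        for k in range(2):
            t = m.scores_[:, k]
            assert abs(t @ yc) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(yc)

    def test_deflation_reduces_variance(self, rng):
        x, y = self._data(rng)
        out = OSC(n_components=1).fit(x, y).transform(x)
        assert np.var(out - out.mean(0)) < np.var(x - x.mean(0))

    def test_transform_uses_frozen_basis(self, rng):
        x, y = self._data(rng)
        m = OSC().fit(x, y)
        w = m.weights_.copy()
        m.transform(rng.standard_normal((5, 30)))
        assert np.array_equal(m.weights_, w)
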