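"""Echo state network contracts and bald-eagle-search convergence."""

import numpy as np
import pytest

from oxispec.bes import BesConfig, bes_optimize
from oxispec.esn import EchoStateRegressor, EsnConfig, esn_fit, run_reservoir
from oxispec.models import BesEsnRegressor, evaluate
from oxispec.simulate import clean_spectrum_template


def _linked_spectra(n=80, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    mda = rng.uniform(0.0, 0.31, n)
    days = rng.integers(1, 8, n)
    x = np.array([clean_spectrum_template(m, d) for m, d in zip(mda, days)])
    if noise:
        x = x + noise * rng.standard_normal(x.shape)
    return x, mda


class TestEsn:
    def test_initial_state_fades_with_zero_input(self):
        cfg = EsnConfig(reservoir_size=50, spectral_radius=0.9, leak_rate=1.0,
                        seed=1)
        rng = np.random.default_rng(2)
        s0 = 1e-3 * rng.standard_normal(50)
        final = run_reservoir(np.zeros((1, 125)), cfg, initial_state=s0)
        assert np.linalg.norm(final) < 1e-6

    def test_infinite_ridge_predicts_training_mean(self):
        x, y = _linked_spectra(40, seed=3)
        cfg = EsnConfig(reservoir_size=30, ridge_lambda=1e12, seed=0)
        model = EchoStateRegressor(config=cfg).fit(x, y)
        assert np.allclose(model.predict(x), y.mean(), atol=1e-4)

    def test_noise_free_capacity(self):
        x, y = _linked_spectra(120, seed=4)
        cfg = EsnConfig(reservoir_size=100, ridge_lambda=1e-8, seed=0)
        model = EchoStateRegressor(config=cfg).fit(x[:90], y[:90])
        r2 = evaluate(y[90:], model.predict(x[90:]))["r2"]
        assert r2 >= 0.99

    def test_seeded_determinism(self):
        x, y = _linked_spectra(30, seed=5, noise=0.005)
        cfg = EsnConfig(reservoir_size=40, seed=7)
        a = EchoStateRegressor(config=cfg).fit(x, y).predict(x)
        b = EchoStateRegressor(config=cfg).fit(x, y).predict(x)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("bad", [
        dict(spectral_radius=1.0), dict(reservoir_size=5),
        dict(leak_rate=0.0), dict(ridge_lambda=-1.0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            EsnConfig(**bad)


class TestBes:
    def test_sphere_convergence(self):
        hits = 0
        for seed in range(10):
            cfg = BesConfig(population=30, iterations=100,
                            bounds=[(-5.0, 5.0)] * 3, seed=seed)
            _, best, _ = bes_optimize(lambda p: float(p @ p), cfg)
            hits += best < 1e-2
        assert hits >= 9

    def test_constant_objective(self):
        cfg = BesConfig(population=5, iterations=5, bounds=[(0.0, 1.0)], seed=0)
        _, best, trace = bes_optimize(lambda p: 3.5, cfg)
        assert best == 3.5
        assert np.all(trace == 3.5)

    def test_trace_monotone_and_bounded_by_initial_population(self):
        cfg = BesConfig(population=8, iterations=20, bounds=[(-3.0, 3.0)] * 2,
                        seed=11)
        obj = lambda p: float((p - 1.0) @ (p - 1.0)) + 0.5  # noqa: E731
        _, best, trace = bes_optimize(obj, cfg)
        assert np.all(np.diff(trace) <= 0)
        # reconstruct the seeded initial population
        rng = np.random.default_rng(11)
        lo, hi = -3.0, 3.0
        init = lo + (hi - lo) * rng.random((8, 2))
        assert best <= min(obj(p) for p in init)

    def test_non_finite_candidates_rejected(self):
        cfg = BesConfig(population=5, iterations=10, bounds=[(-1.0, 1.0)], seed=0)
        def obj(p):
            return np.nan if p[0] > 0 else float(p @ p)
        _, best, _ = bes_optimize(obj, cfg)
        assert np.isfinite(best)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BesConfig(population=2)
        with pytest.raises(ValueError):
            BesConfig(bounds=[(1.0, 0.0)])


class TestBesEsn:
    def test_degenerate_box_equals_plain_esn(self):
        x, y = _linked_spectra(40, seed=6, noise=0.003)
        point = dict(reservoir_size=(40, 40), spectral_radius=(0.8, 0.8),
                     input_scaling=(2.0, 2.0), leak_rate=(0.5, 0.5),
                     log10_ridge=(-3.0, -3.0))
        tuned = BesEsnRegressor(bounds=point, seed=0).fit(x, y)
        plain = esn_fit(x, y, tuned.best_config_)
        assert np.allclose(tuned.predict(x), plain.predict(x), atol=1e-12)

    def test_incomplete_bounds_rejected(self):
        x, y = _linked_spectra(20, seed=1)
        # a bounds dict may extend but never drop required hyperparameters
        model = BesEsnRegressor(bounds={"reservoir_size": (20, 30)},
                                population=4, iterations=1, cv_folds=2, seed=0)
        model.fit(x, y)  # partial dicts merge over defaults
        assert 20 <= model.best_config_.reservoir_size <= 30
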