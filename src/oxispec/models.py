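"""Model evaluation metrics and the BES-tuned echo state network.

Metrics follow the chemometrics convention: R^2 = 1 - SS_res/SS_tot (not a
squared correlation), RMSE = sqrt(SS_res/n), and RPD = sd(reference) / RMSE
on the validation set.  ``BesEsnRegressor`` wraps the bald-eagle search
around cross-validated ESN RMSE over a hyperparameter box covering
reservoir size, spectral radius, input scaling, leak rate and the ridge
penalty (log10 scale), then refits at the optimum on all calibration rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .bes import BesConfig, bes_optimize
from .esn import EchoStateRegressor, EsnConfig
from .pls import _kfold_indices


class UndefinedMetricError(ValueError):
    """R^2 is undefined because the reference values have zero variance."""


def evaluate(y_true, y_pred) -> dict[str, float]:
    """R^2, RMSE and RPD of predictions against reference values."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("zero-variance reference values")
    rmse = float(np.sqrt(ss_res / y_true.size))
    sd = float(np.std(y_true, ddof=1))
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse,
            "rpd": sd / rmse if rmse > 0 else np.inf}


@dataclass
class FitReport:
    """Calibration/prediction metrics of one fitted pipeline configuration."""

    r2_c: float
    rmsec: float
    r2_p: float
    rmsep: float
    rpd: float
    n_variables: int = 0
    lvs: int | None = None

    def as_row(self) -> dict:
        return {"R2_C": self.r2_c, "RMSEC": self.rmsec, "R2_P": self.r2_p,
                "RMSEP": self.rmsep, "RPD": self.rpd,
                "n_variables": self.n_variables, "LVs": self.lvs}


def make_fit_report(y_cal, yhat_cal, y_val, yhat_val,
                    n_variables: int = 0, lvs: int | None = None) -> FitReport:
    cal = evaluate(y_cal, yhat_cal)
    val = evaluate(y_val, yhat_val)
    return FitReport(r2_c=cal["r2"], rmsec=cal["rmse"], r2_p=val["r2"],
                     rmsep=val["rmse"], rpd=val["rpd"],
                     n_variables=n_variables, lvs=lvs)


#: default hyperparameter search box; ridge penalty searched in log10 space
DEFAULT_ESN_BOUNDS: dict[str, tuple[float, float]] = {
    "reservoir_size": (30, 150),
    "spectral_radius": (0.3, 0.98),
    "input_scaling": (0.5, 20.0),
    "leak_rate": (0.1, 1.0),
    "log10_ridge": (-6.0, 2.0),
}


def _decode(point: np.ndarray, names: list[str], fixed: dict[str, float],
            esn_seed: int) -> EsnConfig:
    vals = dict(fixed)
    vals.update(zip(names, point))
    return EsnConfig(reservoir_size=int(round(vals["reservoir_size"])),
                     spectral_radius=float(vals["spectral_radius"]),
                     input_scaling=float(vals["input_scaling"]),
                     leak_rate=float(vals["leak_rate"]),
                     ridge_lambda=10.0 ** float(vals["log10_ridge"]),
                     seed=esn_seed)


def _cv_rmse_esn(x, y, cfg: EsnConfig, fold_sets) -> float:
    n = x.shape[0]
    sse = 0.0
    for val_idx in fold_sets:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        model = EchoStateRegressor(config=cfg).fit(x[mask], y[mask])
        r = model.predict(x[val_idx]) - y[val_idx]
        sse += float(r @ r)
    return np.sqrt(sse / n)


class BesEsnRegressor(BaseEstimator, RegressorMixin):
    """ESN with hyperparameters tuned by bald eagle search over CV RMSE.

    Bounds with equal lower and upper collapse that hyperparameter to a
    constant; if every bound is degenerate the search is skipped and the
    model is a plain ESN at that configuration.
    """

    def __init__(self, bounds: dict[str, tuple[float, float]] | None = None,
                 population: int = 8, iterations: int = 10, cv_folds: int = 3,
                 seed: int = 0):
        self.bounds = bounds
        self.population = population
        self.iterations = iterations
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, x, y):
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        bounds = dict(DEFAULT_ESN_BOUNDS)
        if self.bounds:
            bounds.update(self.bounds)
        missing = set(DEFAULT_ESN_BOUNDS) - set(bounds)
        if missing:
            raise ValueError(f"bounds must cover {sorted(missing)}")
        esn_seed = self.seed + 1000003
        fold_sets = _kfold_indices(x.shape[0], self.cv_folds, self.seed)
        free = [k for k, (lo, hi) in bounds.items() if lo < hi]
        fixed = {k: lo for k, (lo, hi) in bounds.items() if lo >= hi}

        if free:
            def objective(p: np.ndarray) -> float:
                cfg = _decode(p, free, fixed, esn_seed)
                return _cv_rmse_esn(x, y, cfg, fold_sets)

            bes_cfg = BesConfig(population=self.population,
                                iterations=self.iterations,
                                bounds=[bounds[k] for k in free],
                                seed=self.seed)
            best, best_val, trace = bes_optimize(objective, bes_cfg)
            self.search_trace_ = trace
            self.cv_rmse_ = float(best_val)
            self.best_config_ = _decode(best, free, fixed, esn_seed)
        else:
            self.best_config_ = _decode(np.empty(0), [], fixed, esn_seed)
            self.search_trace_ = np.empty(0)
            self.cv_rmse_ = _cv_rmse_esn(x, y, self.best_config_, fold_sets)
        self.model_ = EchoStateRegressor(config=self.best_config_).fit(x, y)
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, x):
        check_is_fitted(self, "model_")
        return self.model_.predict(x)


def bes_esn_fit(x, y, bounds=None, population=8, iterations=10,
                cv_folds: int = 3, seed: int = 0) -> BesEsnRegressor:
    return BesEsnRegressor(bounds=bounds, population=population,
                           iterations=iterations, cv_folds=cv_folds,
                           seed=seed).fit(x, y)
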