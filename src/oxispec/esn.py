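"""Echo state network regression over the wavelength axis.

A spectrum has no time axis, so the reservoir is driven band-by-band in
wavelength order: each reflectance value is one input step of a leaky
tanh reservoir

    s[t+1] = (1 - a) s[t] + a tanh(W_in u[t] + W s[t]),

with the recurrent matrix W rescaled to spectral radius < 1 (echo-state
property: the influence of the initial state fades, so the states are a
deterministic functional of the spectrum).  Inputs are centered on the
calibration mean spectrum so the reservoir operates around its linear
point and responds to the informative reflectance *variation*, not the
large constant pedestal.  The readout is a ridge regression from the state
trajectory (subsampled every ``readout_stride`` bands after the washout)
plus a direct input-to-output connection — both standard ESN practice; the
leaky integration acts as an intrinsic low-pass over the wavelength axis,
which is what makes the model robust to high-frequency packaging-film
interference.  All random matrices derive from the config seed, so a
config fully determines the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class EsnConfig:
    reservoir_size: int = 100
    spectral_radius: float = 0.9
    input_scaling: float = 5.0
    leak_rate: float = 0.5
    ridge_lambda: float = 1e-2
    sparsity: float = 0.1       # fraction of nonzero recurrent weights
    washout: int = 4            # initial bands excluded from the readout
    readout_stride: int = 4     # keep every k-th band's state for the readout
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.spectral_radius < 1:
            raise ValueError("spectral_radius must be in (0, 1)")
        if self.reservoir_size < 10:
            raise ValueError("reservoir_size must be at least 10")
        if not 0 < self.leak_rate <= 1:
            raise ValueError("leak_rate must be in (0, 1]")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")


def _reservoir_matrices(cfg: EsnConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fixed random input/recurrent weights, recurrent rescaled to rho."""
    rng = np.random.default_rng(cfg.seed)
    r = cfg.reservoir_size
    w_in = rng.uniform(-1.0, 1.0, size=r) * cfg.input_scaling
    w = rng.standard_normal((r, r))
    mask = rng.random((r, r)) < cfg.sparsity
    w = np.where(mask, w, 0.0)
    eig = np.max(np.abs(np.linalg.eigvals(w)))
    if eig > 0:
        w *= cfg.spectral_radius / eig
    return w_in, w


def run_reservoir(x: np.ndarray, cfg: EsnConfig,
                  initial_state: np.ndarray | None = None,
                  return_all: bool = False) -> np.ndarray:
    """Drive spectra through the reservoir; returns final states (n, r).

    ``return_all`` yields the state sequence (n, bands - washout, r) with
    the first ``washout`` steps discarded.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n, bands = x.shape
    w_in, w = _reservoir_matrices(cfg)
    a = cfg.leak_rate
    s = np.zeros((n, cfg.reservoir_size)) if initial_state is None else \
        np.broadcast_to(initial_state, (n, cfg.reservoir_size)).copy()
    if return_all:
        seq = np.empty((n, bands, cfg.reservoir_size))
    for t in range(bands):
        s = (1 - a) * s + a * np.tanh(np.outer(x[:, t], w_in) + s @ w.T)
        if return_all:
            seq[:, t, :] = s
    if return_all:
        return seq[:, cfg.washout:, :]
    return s


class EchoStateRegressor(BaseEstimator, RegressorMixin):
    """Reservoir-computing regressor with a trajectory + direct-input readout.

    Readout features per spectrum: the centered input spectrum itself (the
    direct connection) and the reservoir state at every ``readout_stride``-th
    band after the washout.  The ridge solve switches to the dual (kernel)
    form when features outnumber samples.
    """

    def __init__(self, config: EsnConfig | None = None):
        self.config = config

    def _features(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config_
        u = x - self.x_mean_
        seq = run_reservoir(u, cfg, return_all=True)
        states = seq[:, ::cfg.readout_stride, :].reshape(len(u), -1)
        return np.column_stack([u, states])

    def fit(self, x, y):
        self.config_ = self.config if self.config is not None else EsnConfig()
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        self.x_mean_ = x.mean(axis=0)
        feats = self._features(x)
        fm = feats.mean(axis=0)
        ym = y.mean()
        fc = feats - fm
        yc = y - ym
        n, p = fc.shape
        lam = self.config_.ridge_lambda
        if p <= n:
            gram = fc.T @ fc + lam * np.eye(p)
            self.readout_ = np.linalg.solve(gram, fc.T @ yc)
        else:  # dual form: w = Fc' (K + lam I)^-1 yc
            k = fc @ fc.T + lam * np.eye(n)
            alpha = np.linalg.solve(k, yc)
            self.readout_ = fc.T @ alpha
        self.feat_mean_ = fm
        self.y_mean_ = float(ym)
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, x):
        check_is_fitted(self, "readout_")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        feats = self._features(x)
        return (feats - self.feat_mean_) @ self.readout_ + self.y_mean_


def esn_fit(x, y, config: EsnConfig) -> EchoStateRegressor:
    return EchoStateRegressor(config=config).fit(x, y)


def esn_predict(model: EchoStateRegressor, x) -> np.ndarray:
    return model.predict(x)
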