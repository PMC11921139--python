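"""Row-wise spectral pretreatments.

Each pretreatment is a scikit-learn transformer so chains compose with
``sklearn.pipeline.Pipeline``.  SNV, min-max normalization, baseline-offset
removal, detrending and Savitzky-Golay smoothing are row-local (stateless);
MSC and OSC learn state from the calibration rows only (the MSC reference
spectrum, the OSC weight/loading basis) and apply it frozen to new rows —
the leakage boundary the evaluation protocol depends on.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class RowDegeneracyError(ValueError):
    """A row violates a pretreatment's variance/scale precondition."""


def _as2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if not np.all(np.isfinite(x)):
        raise ValueError("spectra must be finite")
    return x


def snv(x) -> np.ndarray:
    """Standard normal variate: per row subtract mean, divide by sd (ddof=1)."""
    x = _as2d(x)
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise RowDegeneracyError(f"zero-variance rows for SNV: {bad.tolist()}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def normalize(x) -> np.ndarray:
    """Per-row min-max scaling to [0, 1]."""
    x = _as2d(x)
    lo = x.min(axis=1, keepdims=True)
    rng = x.max(axis=1, keepdims=True) - lo
    bad = np.flatnonzero(rng.ravel() == 0)
    if bad.size:
        raise RowDegeneracyError(f"flat rows for min-max normalize: {bad.tolist()}")
    return (x - lo) / rng


def baseline(x) -> np.ndarray:
    """Subtract each row's minimum (additive-offset removal)."""
    x = _as2d(x)
    return x - x.min(axis=1, keepdims=True)


def detrend(x, order: int = 2) -> np.ndarray:
    """Subtract a per-row least-squares polynomial in band index."""
    x = _as2d(x)
    b = x.shape[1]
    t = np.arange(b, dtype=np.float64)
    # shared Vandermonde projector: resid = x - x @ P with P = V (V'V)^-1 V'
    v = np.vander(t, order + 1, increasing=True)
    proj, *_ = np.linalg.lstsq(v, x.T, rcond=None)
    return x - (v @ proj).T


def savgol(x, window: int = 11, polyorder: int = 2, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative along the band axis.

    Edges use the polynomial fit on the truncated window (``mode="interp"``).
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    x = _as2d(x)
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=deriv, axis=1, mode="interp")


def _msc_fit_row(row: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Closed-form simple regression row ~ a + b*ref."""
    rm = ref.mean()
    xm = row.mean()
    den = float(((ref - rm) ** 2).sum())
    b = float(((ref - rm) * (row - xm)).sum()) / den
    a = xm - b * rm
    return a, b


class SNV(BaseEstimator, TransformerMixin):
    """Stateless SNV transformer."""

    def fit(self, x, y=None):
        self.n_features_in_ = _as2d(x).shape[1]
        return self

    def transform(self, x):
        return snv(x)


class MinMaxRow(BaseEstimator, TransformerMixin):
    """Per-row min-max normalization ("Normalize" pretreatment)."""

    def fit(self, x, y=None):
        self.n_features_in_ = _as2d(x).shape[1]
        return self

    def transform(self, x):
        return normalize(x)


class BaselineOffset(BaseEstimator, TransformerMixin):
    """Per-row minimum subtraction ("Baseline" pretreatment)."""

    def fit(self, x, y=None):
        self.n_features_in_ = _as2d(x).shape[1]
        return self

    def transform(self, x):
        return baseline(x)


class Detrend(BaseEstimator, TransformerMixin):
    def __init__(self, order: int = 2):
        self.order = order

    def fit(self, x, y=None):
        self.n_features_in_ = _as2d(x).shape[1]
        return self

    def transform(self, x):
        return detrend(x, order=self.order)


class SavGol(BaseEstimator, TransformerMixin):
    def __init__(self, window: int = 11, polyorder: int = 2, deriv: int = 0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv

    def fit(self, x, y=None):
        self.n_features_in_ = _as2d(x).shape[1]
        return self

    def transform(self, x):
        return savgol(x, self.window, self.polyorder, self.deriv)


class MSC(BaseEstimator, TransformerMixin):
    """Multiplicative scatter correction against a fixed reference spectrum.

    ``fit`` freezes the reference (the calibration-set mean spectrum unless
    one is supplied); ``transform`` regresses each row on it and inverts the
    per-row affine map: (row - a) / b.
    """

    def __init__(self, reference: np.ndarray | None = None, min_slope: float = 1e-12):
        self.reference = reference
        self.min_slope = min_slope

    def fit(self, x, y=None):
        x = _as2d(x)
        ref = x.mean(axis=0) if self.reference is None else np.asarray(
            self.reference, dtype=np.float64)
        if ref.std() == 0:
            raise RowDegeneracyError("MSC reference spectrum has zero variance")
        self.reference_ = ref
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, x):
        check_is_fitted(self, "reference_")
        x = _as2d(x)
        out = np.empty_like(x)
        for i, row in enumerate(x):
            a, b = _msc_fit_row(row, self.reference_)
            if abs(b) < self.min_slope:
                raise RowDegeneracyError(f"MSC slope below threshold on row {i}")
            out[i] = (row - a) / b
        return out


class OSC(BaseEstimator, TransformerMixin):
    """Orthogonal signal correction (Wold-style).

    Removes the ``n_components`` strongest x-variation directions that are
    orthogonal to y.  ``fit`` stores per-component weight vectors w and
    loadings p on the calibration rows; ``transform`` deflates new rows with
    that frozen basis (t = X w; X <- X - t p').
    """

    def __init__(self, n_components: int = 1, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, x, y):
        x = _as2d(x).copy()
        y = np.asarray(y, dtype=np.float64).ravel()
        if x.shape[0] < 3:
            raise ValueError("OSC needs at least 3 calibration rows")
        self.x_mean_ = x.mean(axis=0)
        self.y_mean_ = float(y.mean())
        xc = x - self.x_mean_
        yc = y - self.y_mean_
        yy = float(yc @ yc)
        weights, loadings, scores = [], [], []
        for _ in range(self.n_components):
            # dominant principal score of current x as the starting t
            t = xc[:, np.argmax(xc.var(axis=0))].copy()
            converged = False
            for _ in range(self.max_iter):
                t_old = t
                if yy > 0:
                    t = t - yc * (float(yc @ t) / yy)   # orthogonalize to y
                w = xc.T @ t                             # project back to x-space
                w /= np.linalg.norm(w)
                t = xc @ w
                if np.linalg.norm(t - t_old) < self.tol * max(np.linalg.norm(t), 1.0):
                    converged = True
                    break
            if not converged:
                raise ArithmeticError(
                    f"OSC component failed to converge in {self.max_iter} iterations")
            if yy > 0:
                t = t - yc * (float(yc @ t) / yy)
            p = xc.T @ t / float(t @ t)
            xc = xc - np.outer(t, p)
            weights.append(w)
            loadings.append(p)
            scores.append(t)
        self.weights_ = np.column_stack(weights)
        self.loadings_ = np.column_stack(loadings)
        self.scores_ = np.column_stack(scores)
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, x):
        check_is_fitted(self, "weights_")
        xc = _as2d(x) - self.x_mean_
        for k in range(self.weights_.shape[1]):
            t = xc @ self.weights_[:, k]
            xc = xc - np.outer(t, self.loadings_[:, k])
        return xc + self.x_mean_


_PRETREATMENTS = {
    "snv": SNV,
    "normalize": MinMaxRow,
    "baseline": BaselineOffset,
    "detrend": Detrend,
    "savgol": SavGol,
    "msc": MSC,
    "osc": OSC,
}


def make_pretreatment(name: str, **params):
    """Instantiate a pretreatment transformer by its config name."""
    try:
        cls = _PRETREATMENTS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown pretreatment {name!r}; known: {sorted(_PRETREATMENTS)}") from None
    return cls(**params)
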