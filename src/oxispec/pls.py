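"""Partial least squares regression (PLS1) with a SIMPLS core.

PLSR is the workhorse model of Vis-NIR chemometrics: it projects the
collinear reflectance bands onto a small number of latent variables (LVs)
that maximize covariance with the response, then regresses the response on
those scores.  The SIMPLS formulation used here produces, in a single fit,
the regression coefficient vector for *every* LV count up to ``max_lv`` —
which is what makes Monte-Carlo wavelength selectors (hundreds of
cross-validated refits on band subsets) affordable.

For a univariate response SIMPLS and NIPALS give the same model; the
scikit-learn NIPALS implementation serves as an independent cross-check in
the test suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def simpls_coefficients(x: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    """Cumulative SIMPLS coefficients for 1..n_lv latent variables.

    Parameters
    ----------
    x : (n, b) array — *centered* predictor matrix.
    y : (n,) array — *centered* response.
    n_lv : number of latent variables to extract.

    Returns
    -------
    (b, n_lv) array ``B`` where ``x @ B[:, k-1]`` is the centered
    prediction using k latent variables.  If the residual covariance
    collapses before ``n_lv`` components, remaining columns repeat the last
    valid one (the model has converged to the OLS solution on the spanned
    space).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = x.shape
    a = int(min(n_lv, n - 1, b))
    if a < 1:
        raise ValueError("need at least one latent variable and n >= 2")

    s = x.T @ y                      # b-vector: covariance X'y
    coefs = np.empty((b, n_lv))
    basis = np.empty((b, a))         # orthonormalized loadings (for deflation)
    bcur = np.zeros(b)
    k_done = 0
    for k in range(a):
        r = s.copy()
        t = x @ r
        tt = t @ t
        if tt <= 1e-14 * n:
            break
        norm_t = np.sqrt(tt)
        t /= norm_t
        r /= norm_t
        p = x.T @ t                  # loading
        q = y @ t                    # scalar regression of y on score
        v = p.copy()
        if k > 0:
            v -= basis[:, :k] @ (basis[:, :k].T @ p)
        nv = np.linalg.norm(v)
        if nv <= 1e-14:
            break
        v /= nv
        basis[:, k] = v
        s -= v * (v @ s)
        bcur = bcur + r * q
        coefs[:, k] = bcur
        k_done = k + 1
    if k_done == 0:
        coefs[:, 0] = 0.0
        k_done = 1
    for k in range(k_done, n_lv):
        coefs[:, k] = coefs[:, k_done - 1]
    return coefs


def _kfold_indices(n: int, folds: int, seed: int | None) -> list[np.ndarray]:
    """Contiguous-size, shuffled K-fold assignment; seed=None means unshuffled."""
    idx = np.arange(n)
    if seed is not None:
        np.random.default_rng(seed).shuffle(idx)
    return [idx[k::folds] for k in range(folds)]


def cv_rmse_by_lv(
    x: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: int = 5,
    seed: int | None = 0,
    fold_sets: list[np.ndarray] | None = None,
) -> np.ndarray:
    """RMSECV for every LV count 1..max_lv in one pass.

    ``fold_sets`` may be supplied so that competing band subsets are scored
    on identical folds (required for comparable RMSECV traces across
    selectors within one run).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = x.shape
    if fold_sets is None:
        fold_sets = _kfold_indices(n, folds, seed)
    max_lv = int(min(max_lv, b, n - max(len(f) for f in fold_sets) - 1))
    max_lv = max(max_lv, 1)
    sse = np.zeros(max_lv)
    for val_idx in fold_sets:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        xt, yt = x[mask], y[mask]
        xm = xt.mean(axis=0)
        ym = yt.mean()
        coefs = simpls_coefficients(xt - xm, yt - ym, max_lv)
        pred = (x[val_idx] - xm) @ coefs + ym          # (n_val, max_lv)
        resid = pred - y[val_idx][:, None]
        sse += (resid * resid).sum(axis=0)
    return np.sqrt(sse / n)


def rmsecv(x, y, max_lv, folds=5, seed=0, fold_sets=None) -> tuple[float, int]:
    """Minimum RMSECV over LV counts and the LV achieving it (first on ties)."""
    curve = cv_rmse_by_lv(x, y, max_lv, folds=folds, seed=seed, fold_sets=fold_sets)
    k = int(np.argmin(curve))
    return float(curve[k]), k + 1


def select_lv_by_cv(x, y, max_lv: int = 20, folds: int = 5, seed: int | None = 0) -> int:
    """Choose the LV count at the first RMSECV minimum."""
    _, lv = rmsecv(x, y, max_lv, folds=folds, seed=seed)
    return lv


class PLSRegressor(BaseEstimator, RegressorMixin):
    """SIMPLS partial least squares regressor for a single response.

    Parameters
    ----------
    n_lv : int or "cv"
        Number of latent variables; ``"cv"`` selects it by K-fold RMSECV
        (first minimum), capped at ``max_lv``.
    max_lv : int
        Upper bound on LVs when ``n_lv="cv"``.
    cv_folds : int
        Folds for the LV search.
    cv_seed : int or None
        Seed for the fold shuffle; None keeps input order.
    """

    def __init__(self, n_lv: int | str = "cv", max_lv: int = 20,
                 cv_folds: int = 5, cv_seed: int | None = 0):
        self.n_lv = n_lv
        self.max_lv = max_lv
        self.cv_folds = cv_folds
        self.cv_seed = cv_seed

    def fit(self, x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError("x must be 2-D with one row per response value")
        if x.shape[0] < 2:
            raise ValueError("need at least two samples")
        if self.n_lv == "cv":
            lv = select_lv_by_cv(x, y, self.max_lv, self.cv_folds, self.cv_seed)
        else:
            lv = int(self.n_lv)
            if lv < 1 or lv > min(x.shape[0] - 1, x.shape[1]):
                raise ValueError(f"n_lv={lv} out of range for data {x.shape}")
        self.x_mean_ = x.mean(axis=0)
        self.y_mean_ = float(y.mean())
        coefs = simpls_coefficients(x - self.x_mean_, y - self.y_mean_, lv)
        self.coef_path_ = coefs
        self.coef_ = coefs[:, lv - 1]
        self.n_lv_ = lv
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, x):
        check_is_fitted(self, "coef_")
        x = np.asarray(x, dtype=np.float64)
        return (x - self.x_mean_) @ self.coef_ + self.y_mean_


def plsr_fit(x, y, n_lv) -> PLSRegressor:
    """Functional wrapper: fit a PLSRegressor with a fixed LV count."""
    return PLSRegressor(n_lv=n_lv).fit(x, y)


def plsr_predict(model: PLSRegressor, x):
    return model.predict(x)
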