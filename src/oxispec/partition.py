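"""Monte-Carlo outlier rejection and SPXY calibration/validation splitting.

Outliers are flagged by repeated random-subset PLSR: each round fits on a
random 75% of samples and predicts the held-out 25%; samples whose
prediction-residual mean or spread is extreme (robust z-score over the
median/MAD) are rejected.  The remaining samples are split by SPXY — a
Kennard-Stone greedy max-min selection on a joint x/y distance — which
places the most mutually distant samples in the calibration set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .pls import simpls_coefficients


class DegenerateDataError(ValueError):
    """All samples were flagged as outliers."""


@dataclass
class OutlierDiagnostics:
    residual_mean: np.ndarray
    residual_sd: np.ndarray
    z_mean: np.ndarray
    z_sd: np.ndarray


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    diagnostics: OutlierDiagnostics | None = None


def _robust_z(v: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Median/MAD z-scores; a scale floor keeps numerically-zero residual
    spreads (exactly linear data) from producing spurious flags."""
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    scale = max(1.4826 * mad, np.std(v) * 1e-6, floor)
    return (v - med) / scale


def mc_outlier_removal(x, y, n_rounds: int = 500, train_frac: float = 0.75,
                       max_lv: int = 10, z_cut: float = 3.0,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray, OutlierDiagnostics]:
    """Flag anomalous samples by Monte-Carlo cross-prediction residuals.

    Returns (kept_indices, outlier_indices, diagnostics); deterministic
    under ``seed``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 10:
        raise ValueError("Monte-Carlo outlier screening needs at least 10 samples")
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_frac * n)))
    lv = int(min(max_lv, n_train - 1, x.shape[1]))
    res_sum = np.zeros(n)
    res_sq = np.zeros(n)
    res_cnt = np.zeros(n)
    for _ in range(n_rounds):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        xm = x[tr].mean(axis=0)
        ym = y[tr].mean()
        coef = simpls_coefficients(x[tr] - xm, y[tr] - ym, lv)[:, -1]
        r = (x[te] - xm) @ coef + ym - y[te]
        res_sum[te] += r
        res_sq[te] += r * r
        res_cnt[te] += 1
    res_cnt = np.maximum(res_cnt, 1)
    mean = res_sum / res_cnt
    var = np.maximum(res_sq / res_cnt - mean**2, 0.0)
    sd = np.sqrt(var)
    floor = max(float(np.std(y)), 1.0) * 1e-6
    z_mean = _robust_z(mean, floor)
    z_sd = _robust_z(sd, floor)
    flagged = (np.abs(z_mean) > z_cut) | (z_sd > z_cut)
    diag = OutlierDiagnostics(mean, sd, z_mean, z_sd)
    if flagged.all():
        raise DegenerateDataError("every sample flagged as an outlier")
    return np.flatnonzero(~flagged), np.flatnonzero(flagged), diag


def spxy_split(x, y, ratio_cal: int = 3, ratio_val: int = 1) -> SplitResult:
    """SPXY (joint x-y distance Kennard-Stone) calibration/validation split.

    Distance d(i,j) = dx(i,j)/max(dx) + dy(i,j)/max(dy) with Euclidean dx
    and absolute-difference dy.  Selection is greedy max-min, seeded by the
    most distant pair; ties break toward the smallest index.  The
    calibration count is floor(n * ratio_cal / (ratio_cal + ratio_val)),
    e.g. 153 samples at 3:1 give 114/39.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 4:
        raise ValueError("SPXY needs at least 4 samples")
    dx = squareform(pdist(x, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    max_dx = dx.max()
    max_dy = dy.max()
    if max_dy <= 0:
        warnings.warn("response has zero variance; SPXY falls back to x-only "
                      "distances", stacklevel=2)
        d = dx / max_dx
    else:
        d = dx / max_dx + dy / max_dy

    n_cal = int(np.floor(n * ratio_cal / (ratio_cal + ratio_val)))
    n_cal = min(max(n_cal, 2), n - 1)
    # seed pair: maximum distance, smallest (i, j) on ties
    flat = np.argmax(d)          # argmax scans row-major -> smallest index pair
    i, j = divmod(flat, n)
    selected = [min(i, j), max(i, j)]
    in_sel = np.zeros(n, dtype=bool)
    in_sel[selected] = True
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        min_d_masked = np.where(in_sel, -np.inf, min_d)
        k = int(np.argmax(min_d_masked))     # first max -> smallest index tie-break
        selected.append(k)
        in_sel[k] = True
        min_d = np.minimum(min_d, d[k])
    cal = np.array(sorted(selected))
    val = np.flatnonzero(~in_sel)
    return SplitResult(calibration_indices=cal, validation_indices=val)
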