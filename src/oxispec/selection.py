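"""Characteristic-wavelength selection: CARS, iVISSA and VCPA.

All three wrap cross-validated PLSR (shared, seeded fold assignment so
RMSECV values are comparable across selectors within a run):

* CARS — Monte-Carlo PLS fits on random sample subsets; a forced
  exponentially decreasing schedule (EDF) keeps the top bands by
  |regression coefficient| and adaptive reweighted sampling (ARS) draws
  among them; the subset with minimal RMSECV over all runs wins.
* iVISSA — weighted binary matrix sampling: per-band inclusion weights
  (initially 0.5) are updated to the frequency of each band among the best
  10% of random band-inclusion draws; after the global iterations an
  optional local stage greedily widens selected bands into contiguous
  intervals while RMSECV does not worsen.
* VCPA — binary matrix sampling over a surviving band pool that an EDF
  schedule shrinks toward ``final_pool``; the winner is the best subset in
  an exhaustive search over all non-empty combinations of the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .pls import _kfold_indices, cv_rmse_by_lv


def band_share(n_selected: int, n_bands: int = 125) -> float:
    """Share of the full band count, in percent rounded to one decimal."""
    return round(100.0 * n_selected / n_bands, 1)


@dataclass
class SelectionResult:
    selected: np.ndarray
    rmsecv_trace: np.ndarray
    subset_history: list[np.ndarray]
    best_iteration: int
    best_rmsecv: float
    best_lv: int
    fold_sets: list[np.ndarray] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size == 0:
            raise ValueError("selection must be non-empty")


def _subset_rmsecv(x, y, cols, max_lv, fold_sets) -> tuple[float, int]:
    curve = cv_rmse_by_lv(x[:, cols], y, max_lv, fold_sets=fold_sets)
    k = int(np.argmin(curve))
    return float(curve[k]), k + 1


def cars_edf_schedule(n_bands: int, n_runs: int) -> np.ndarray:
    """Forced retained-band counts r_i = b * (b/2)^(-(i-1)/(N-1)).

    Non-increasing from b down to 2.
    """
    i = np.arange(n_runs, dtype=np.float64)
    counts = np.round(n_bands * (n_bands / 2.0) ** (-i / (n_runs - 1))).astype(int)
    return np.maximum(counts, 2)


def cars_select(x, y, n_runs: int = 500, max_lv: int = 20, cv_folds: int = 20,
                centering: bool = True, seed: int = 0,
                train_frac: float = 0.8) -> SelectionResult:
    """Competitive adaptive reweighted sampling."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = x.shape
    if n < cv_folds:
        raise ValueError("need at least cv_folds samples")
    fold_sets = _kfold_indices(n, cv_folds, seed)
    rng = np.random.default_rng([seed, 1])
    schedule = cars_edf_schedule(b, n_runs)
    n_sub = max(2, int(round(train_frac * n)))

    retained = np.arange(b)
    trace = np.empty(n_runs)
    history: list[np.ndarray] = []
    lvs = np.empty(n_runs, dtype=int)
    for i in range(n_runs):
        # score the current subset on the shared folds
        rmse, lv = _subset_rmsecv(x, y, retained, max_lv, fold_sets)
        trace[i] = rmse
        lvs[i] = lv
        history.append(retained.copy())
        if i == n_runs - 1:
            break
        # Monte-Carlo coefficient estimate on a random sample subset
        sub = rng.choice(n, size=n_sub, replace=False)
        xs = x[sub][:, retained]
        ys = y[sub]
        xm = xs.mean(axis=0) if centering else 0.0
        ym = ys.mean() if centering else 0.0
        from .pls import simpls_coefficients
        lv_fit = int(min(lv, n_sub - 1, retained.size))
        coef = np.abs(simpls_coefficients(xs - xm, ys - ym, lv_fit)[:, -1])
        # EDF: forced retention of the top r bands by |coefficient|
        r = int(min(schedule[i + 1], retained.size))
        top = np.argsort(-coef, kind="stable")[:r]
        retained_edf = retained[np.sort(top)]
        coef_edf = coef[np.sort(top)]
        # ARS: weighted draw with replacement among retained, de-duplicated
        w = coef_edf.copy()
        if w.sum() <= 0:
            w = np.ones_like(w)
        w = w / w.sum()
        draw = rng.choice(retained_edf.size, size=r, replace=True, p=w)
        keep = np.unique(draw)
        if keep.size < 2:
            keep = np.argsort(-coef_edf, kind="stable")[:2]
        retained = retained_edf[np.sort(keep)]
    best = int(np.argmin(trace))
    return SelectionResult(selected=np.sort(history[best]), rmsecv_trace=trace,
                           subset_history=history, best_iteration=best,
                           best_rmsecv=float(trace[best]), best_lv=int(lvs[best]),
                           fold_sets=fold_sets,
                           extras={"edf_schedule": schedule})


def _bms_draws(rng, n_draws: int, probs: np.ndarray) -> np.ndarray:
    """Binary inclusion draws; empty rows get one random band enabled."""
    draws = rng.random((n_draws, probs.size)) < probs
    empty = ~draws.any(axis=1)
    if empty.any():
        cols = rng.integers(0, probs.size, size=int(empty.sum()))
        draws[np.flatnonzero(empty), cols] = True
    return draws


def ivissa_select(x, y, max_lv: int = 20, n_iterations: int = 10,
                  n_bms: int = 1000, cv_folds: int = 5, seed: int = 0,
                  elite_frac: float = 0.1, local: bool = True) -> SelectionResult:
    """Interval variable iterative space shrinkage approach (WBMS form)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = x.shape
    fold_sets = _kfold_indices(n, cv_folds, seed)
    rng = np.random.default_rng([seed, 2])
    w = np.full(b, 0.5)
    trace = []
    history: list[np.ndarray] = []
    weight_history = [w.copy()]
    n_elite = max(1, int(round(elite_frac * n_bms)))
    best_draw, best_draw_rmse, best_draw_lv = None, np.inf, 1
    for _ in range(n_iterations):
        draws = _bms_draws(rng, n_bms, w)
        rmses = np.empty(n_bms)
        lvs = np.empty(n_bms, dtype=int)
        for k in range(n_bms):
            cols = np.flatnonzero(draws[k])
            rmses[k], lvs[k] = _subset_rmsecv(x, y, cols, max_lv, fold_sets)
        order = np.argsort(rmses, kind="stable")
        elite = draws[order[:n_elite]]
        w = elite.mean(axis=0)
        trace.append(float(rmses[order[0]]))
        history.append(np.flatnonzero(draws[order[0]]))
        weight_history.append(w.copy())
        if rmses[order[0]] < best_draw_rmse:
            best_draw_rmse = float(rmses[order[0]])
            best_draw = np.flatnonzero(draws[order[0]])
            best_draw_lv = int(lvs[order[0]])
    selected = np.flatnonzero(w >= 0.5)
    if selected.size == 0:
        import warnings
        warnings.warn("iVISSA weights collapsed; falling back to best draw",
                      stacklevel=2)
        selected = best_draw
    rmse_sel, lv_sel = _subset_rmsecv(x, y, selected, max_lv, fold_sets)
    if local:
        improved = True
        while improved:
            improved = False
            neighbors = np.unique(np.concatenate([selected - 1, selected + 1]))
            neighbors = neighbors[(neighbors >= 0) & (neighbors < b)]
            neighbors = np.setdiff1d(neighbors, selected)
            for cand in neighbors:
                trial = np.sort(np.append(selected, cand))
                r_t, lv_t = _subset_rmsecv(x, y, trial, max_lv, fold_sets)
                if r_t <= rmse_sel:
                    selected, rmse_sel, lv_sel = trial, r_t, lv_t
                    improved = True
    trace.append(rmse_sel)
    history.append(selected.copy())
    return SelectionResult(selected=np.sort(selected), rmsecv_trace=np.array(trace),
                           subset_history=history,
                           best_iteration=len(trace) - 1, best_rmsecv=rmse_sel,
                           best_lv=lv_sel, fold_sets=fold_sets,
                           extras={"weight_history": weight_history,
                                   "final_weights": w})


def vcpa_pool_schedule(n_bands: int, final_pool: int, n_rounds: int) -> np.ndarray:
    """Strictly decreasing EDF pool sizes from n_bands to final_pool."""
    if final_pool >= n_bands:
        raise ValueError("final_pool must be below the band count")
    rho = (final_pool / n_bands) ** (1.0 / n_rounds)
    sizes = []
    prev = n_bands
    for r in range(1, n_rounds + 1):
        target = int(round(n_bands * rho**r))
        nxt = max(final_pool, min(prev - 1, target))
        sizes.append(nxt)
        prev = nxt
        if nxt == final_pool:   # schedule ends at the first touch
            break
    sizes[-1] = final_pool
    return np.array(sizes, dtype=int)


def _subset_fold_rmses(x, y, cols, max_lv, fold_sets) -> np.ndarray:
    """Per-fold RMSE at the CV-chosen LV count for one band subset."""
    xs = x[:, cols]
    n = xs.shape[0]
    curve = cv_rmse_by_lv(xs, y, max_lv, fold_sets=fold_sets)
    lv = int(np.argmin(curve)) + 1
    out = np.empty(len(fold_sets))
    for f, val_idx in enumerate(fold_sets):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        from .pls import simpls_coefficients
        xm = xs[mask].mean(axis=0)
        ym = y[mask].mean()
        coef = simpls_coefficients(xs[mask] - xm, y[mask] - ym,
                                   min(lv, int(mask.sum()) - 1, xs.shape[1]))[:, -1]
        r = (xs[val_idx] - xm) @ coef + ym - y[val_idx]
        out[f] = np.sqrt(np.mean(r * r))
    return out


def vcpa_select(x, y, max_lv: int = 10, n_bms: int = 1000,
                n_edf_rounds: int = 50, final_pool: int = 14,
                cv_folds: int = 5, seed: int = 0,
                elite_frac: float = 0.1,
                parsimony_se: float = 1.0) -> SelectionResult:
    """Variable combination population analysis.

    The exhaustive final stage applies a one-standard-error parsimony rule:
    among subsets whose RMSECV is within ``parsimony_se`` fold-level
    standard errors of the minimum, the smallest subset wins (the strict
    argmin and its RMSECV are kept in ``extras``).  Set ``parsimony_se=0``
    for the plain argmin.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = x.shape
    if final_pool < 1 or final_pool >= b:
        raise ValueError("bad EDF parameters: final_pool out of range")
    fold_sets = _kfold_indices(n, cv_folds, seed)
    rng = np.random.default_rng([seed, 3])
    schedule = vcpa_pool_schedule(b, final_pool, n_edf_rounds)
    pool = np.arange(b)
    trace = []
    history: list[np.ndarray] = []
    n_elite = max(1, int(round(elite_frac * n_bms)))
    for pool_size in schedule:
        draws = _bms_draws(rng, n_bms, np.full(pool.size, 0.5))
        rmses = np.empty(n_bms)
        for k in range(n_bms):
            cols = pool[np.flatnonzero(draws[k])]
            rmses[k], _ = _subset_rmsecv(x, y, cols, max_lv, fold_sets)
        order = np.argsort(rmses, kind="stable")
        freq = draws[order[:n_elite]].mean(axis=0)
        keep = np.sort(np.argsort(-freq, kind="stable")[:pool_size])
        pool = pool[keep]
        trace.append(float(rmses[order[0]]))
        history.append(pool.copy())
    # exhaustive search over the survivors
    m = pool.size
    subsets: list[np.ndarray] = []
    rmses_all = np.empty(2**m - 1)
    lvs_all = np.empty(2**m - 1, dtype=int)
    for code in range(1, 2**m):
        cols = pool[[k for k in range(m) if code >> k & 1]]
        subsets.append(cols)
        rmses_all[code - 1], lvs_all[code - 1] = _subset_rmsecv(
            x, y, cols, max_lv, fold_sets)
    argmin = int(np.argmin(rmses_all))
    min_rmse = float(rmses_all[argmin])
    if parsimony_se > 0:
        fold_rmses = _subset_fold_rmses(x, y, subsets[argmin], max_lv, fold_sets)
        se = float(np.std(fold_rmses, ddof=1)) / np.sqrt(len(fold_sets))
        within = np.flatnonzero(rmses_all <= min_rmse + parsimony_se * se)
        sizes = np.array([subsets[i].size for i in within])
        best_i = int(within[np.argmin(sizes)])   # smallest subset, first on ties
    else:
        best_i = argmin
    best_subset = subsets[best_i]
    best_rmse = float(rmses_all[best_i])
    best_lv = int(lvs_all[best_i])
    trace.append(best_rmse)
    history.append(np.sort(best_subset))
    return SelectionResult(selected=np.sort(best_subset), rmsecv_trace=np.array(trace),
                           subset_history=history, best_iteration=len(trace) - 1,
                           best_rmsecv=best_rmse, best_lv=best_lv,
                           fold_sets=fold_sets,
                           extras={"pool_schedule": schedule, "final_pool": pool,
                                   "argmin_subset": np.sort(subsets[argmin]),
                                   "argmin_rmsecv": min_rmse})


_SELECTORS = {"cars": cars_select, "ivissa": ivissa_select, "vcpa": vcpa_select}


class WavelengthSelector(BaseEstimator, TransformerMixin):
    """Transformer facade over one of the selection algorithms.

    ``method`` is "cars", "ivissa" or "vcpa"; ``params`` is an optional dict
    of keyword arguments forwarded to the functional interface.  After
    ``fit``, ``selected_`` holds sorted band indices and ``transform``
    subsets columns.
    """

    def __init__(self, method: str = "cars", seed: int = 0,
                 params: dict | None = None):
        self.method = method
        self.seed = seed
        self.params = params

    def fit(self, x, y):
        try:
            fn = _SELECTORS[self.method]
        except KeyError:
            raise ValueError(f"unknown selector {self.method!r}") from None
        self.result_ = fn(x, y, seed=self.seed, **(self.params or {}))
        self.selected_ = self.result_.selected
        self.n_features_in_ = np.asarray(x).shape[1]
        return self

    def transform(self, x):
        check_is_fitted(self, "selected_")
        return np.asarray(x)[:, self.selected_]

    def get_support(self):
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
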