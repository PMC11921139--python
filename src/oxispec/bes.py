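"""Bald eagle search (BES) metaheuristic.

Population optimizer with three phases per iteration, mimicking an eagle
hunt: *select* (move toward the mean of the population, biased by the best
point), *search* (spiral flight around the mean, polar angle/radius set by
``a_param``/``R_param``) and *swoop* (dive toward the best point).  Each
candidate move is accepted greedily only if it improves that eagle's
fitness, so the best value is non-increasing across iterations.  Positions
are clipped to the search box; non-finite objective values reject the
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class BesConfig:
    population: int = 20
    iterations: int = 50
    alpha: float = 2.0       # select-phase attraction strength
    a_param: float = 10.0    # spiral angular frequency
    R_param: float = 1.5     # spiral radius gain
    bounds: list[tuple[float, float]] = field(default_factory=lambda: [(-1.0, 1.0)])
    seed: int = 0

    def __post_init__(self):
        if self.population < 4:
            raise ValueError("population must be at least 4")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")


def _polar(rng, n: int, a: float, r_gain: float) -> tuple[np.ndarray, np.ndarray]:
    """Spiral coordinates x(i), y(i) normalized to max magnitude 1."""
    theta = a * np.pi * rng.random(n)
    r = theta + r_gain * rng.random(n)
    xr = r * np.sin(theta)
    yr = r * np.cos(theta)
    return xr / (np.max(np.abs(xr)) + 1e-300), yr / (np.max(np.abs(yr)) + 1e-300)


def bes_optimize(objective: Callable[[np.ndarray], float],
                 config: BesConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over the box; returns (best_point, best_value, trace).

    ``trace[i]`` is the best value after iteration i (monotone
    non-increasing).  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    dim = lo.size
    npop = config.population

    def safe_eval(p: np.ndarray) -> float:
        v = objective(p)
        return float(v) if np.isfinite(v) else np.inf

    pos = lo + (hi - lo) * rng.random((npop, dim))
    fit = np.array([safe_eval(p) for p in pos])
    ibest = int(np.argmin(fit))
    best, best_val = pos[ibest].copy(), float(fit[ibest])
    trace = np.empty(config.iterations)

    for it in range(config.iterations):
        mean = pos.mean(axis=0)
        # phase 1: select space
        for i in range(npop):
            cand = best + config.alpha * rng.random() * (mean - pos[i])
            cand = np.clip(cand, lo, hi)
            v = safe_eval(cand)
            if v < fit[i]:
                pos[i], fit[i] = cand, v
                if v < best_val:
                    best, best_val = cand.copy(), v
        # phase 2: spiral search in space
        mean = pos.mean(axis=0)
        xs, ys = _polar(rng, npop, config.a_param, config.R_param)
        for i in range(npop):
            j = (i + 1) % npop
            cand = pos[i] + ys[i] * (pos[i] - pos[j]) + xs[i] * (pos[i] - mean)
            cand = np.clip(cand, lo, hi)
            v = safe_eval(cand)
            if v < fit[i]:
                pos[i], fit[i] = cand, v
                if v < best_val:
                    best, best_val = cand.copy(), v
        # phase 3: swoop toward the best point
        mean = pos.mean(axis=0)
        xs, ys = _polar(rng, npop, config.a_param, config.R_param)
        c1, c2 = 2 * rng.random(), 2 * rng.random()
        for i in range(npop):
            cand = (rng.random() * best
                    + xs[i] * (pos[i] - c1 * mean)
                    + ys[i] * (pos[i] - c2 * best))
            cand = np.clip(cand, lo, hi)
            v = safe_eval(cand)
            if v < fit[i]:
                pos[i], fit[i] = cand, v
                if v < best_val:
                    best, best_val = cand.copy(), v
        trace[it] = best_val
    return best, best_val, trace
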