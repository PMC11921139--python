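"""End-to-end orchestration: simulate -> partition -> filter/pretreat ->
select -> fit -> evaluate, with seeded stages and a self-describing manifest.

One global seed fans out to per-stage seeds through a fixed documented
derivation (``stage_seed``), so e.g. changing only the selector seed leaves
the data split untouched.  A run produces a :class:`FitReport` and a JSON-
serializable manifest recording the full configuration, derived seeds,
selected bands and metrics; re-running a manifest's configuration
reproduces the metrics exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from . import __version__
from .filters import FilterSpec, SpectralFilter
from .models import BesEsnRegressor, FitReport, make_fit_report
from .partition import mc_outlier_removal, spxy_split
from .pls import PLSRegressor
from .preprocess import make_pretreatment
from .selection import WavelengthSelector
from .simulate import GeneratorConfig, SpectraDataset, generate_dataset

_STAGE_OFFSETS = {"generator": 11, "outlier": 23, "selector": 37, "model": 53}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed * 1009 + offset) mod 2^31."""
    return (int(seed) * 1009 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one modeling run (one row of a comparison table)."""

    group: str = "blank"
    filter_spec: FilterSpec | None = None
    pretreatments: list[tuple[str, dict]] = field(default_factory=list)
    selector: str | None = None                 # none | cars | ivissa | vcpa
    selector_params: dict = field(default_factory=dict)
    model: str = "plsr"                         # plsr | bes_esn
    model_params: dict = field(default_factory=dict)
    remove_outliers: bool = True
    mc_rounds: int = 500
    ratio_cal: int = 3
    ratio_val: int = 1
    seed: int = 0
    generator: GeneratorConfig | None = None

    def label(self) -> str:
        parts = [self.group,
                 self.filter_spec.kind if self.filter_spec else "nofilter",
                 "+".join(name for name, _ in self.pretreatments) or "raw",
                 self.selector or "full", self.model]
        return "-".join(parts)


def build_model_pipeline(config: RunConfig) -> Pipeline:
    """Assemble the sklearn Pipeline for one run configuration."""
    steps = []
    if config.filter_spec is not None:
        steps.append(("filter", SpectralFilter(spec=config.filter_spec)))
    for name, params in config.pretreatments:
        steps.append((name, make_pretreatment(name, **params)))
    if config.selector:
        steps.append(("selector", WavelengthSelector(
            method=config.selector, seed=stage_seed(config.seed, "selector"),
            params=config.selector_params)))
    if config.model == "plsr":
        steps.append(("model", PLSRegressor(**config.model_params)))
    elif config.model == "bes_esn":
        steps.append(("model", BesEsnRegressor(
            seed=stage_seed(config.seed, "model"), **config.model_params)))
    else:
        raise ValueError(f"unknown model {config.model!r}")
    return Pipeline(steps)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run_pipeline(config: RunConfig,
                 data: SpectraDataset | None = None
                 ) -> tuple[FitReport, dict[str, Any], Pipeline]:
    """Execute one full run; returns (report, manifest, fitted pipeline)."""
    try:
        if data is None:
            gen = config.generator or GeneratorConfig(
                seed=stage_seed(config.seed, "generator"))
            data = generate_dataset(gen)
        ds = data.subset(config.group)
        x, y = ds.x, ds.y
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"simulate/ingest: {exc}") from exc

    outliers = np.array([], dtype=int)
    try:
        if config.remove_outliers:
            kept, outliers, _ = mc_outlier_removal(
                x, y, n_rounds=config.mc_rounds,
                seed=stage_seed(config.seed, "outlier"))
            x, y = x[kept], y[kept]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"outlier-removal: {exc}") from exc

    try:
        split = spxy_split(x, y, config.ratio_cal, config.ratio_val)
        xc, yc = x[split.calibration_indices], y[split.calibration_indices]
        xv, yv = x[split.validation_indices], y[split.validation_indices]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"partition: {exc}") from exc

    try:
        pipe = build_model_pipeline(config)
        pipe.fit(xc, yc)
        yhat_c = pipe.predict(xc)
        yhat_v = pipe.predict(xv)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"fit/predict: {exc}") from exc

    if config.selector:
        selected = pipe.named_steps["selector"].selected_
        n_vars = int(selected.size)
    else:
        selected = np.arange(x.shape[1])
        n_vars = x.shape[1]
    model = pipe.named_steps["model"]
    lvs = getattr(model, "n_lv_", None)
    report = make_fit_report(yc, yhat_c, yv, yhat_v, n_variables=n_vars, lvs=lvs)

    manifest = {
        "oxispec_version": __version__,
        "config": _config_dict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
        "n_samples": int(x.shape[0]),
        "n_outliers_removed": int(outliers.size),
        "calibration_size": int(split.calibration_indices.size),
        "validation_size": int(split.validation_indices.size),
        "selected_bands": selected.tolist(),
        "selected_nm": np.round(data.wavelengths_nm[selected], 2).tolist(),
        "metrics": report.as_row(),
    }
    return report, manifest, pipe


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.filter_spec is not None:
        fs = d["filter_spec"]
        if fs.get("taps") is not None:
            fs["taps"] = np.asarray(fs["taps"]).tolist()
    if config.generator is not None:
        d["generator"] = dataclasses.asdict(config.generator)
    return d


def compare_table(runs: list[tuple[str, FitReport]]) -> pd.DataFrame:
    """One row per (label, report), in input order."""
    cols = ["label", "R2_C", "RMSEC", "R2_P", "RMSEP", "RPD", "n_variables", "LVs"]
    rows = [{"label": label, **report.as_row()} for label, report in runs]
    return pd.DataFrame(rows, columns=cols)


def run_grid(configs: list[RunConfig],
             data: SpectraDataset | None = None) -> pd.DataFrame:
    """Run every configuration (optionally on shared data) into one table."""
    rows = []
    for cfg in configs:
        report, _, _ = run_pipeline(cfg, data=data)
        rows.append((cfg.label(), report))
    return compare_table(rows)
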