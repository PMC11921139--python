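# oxispec

Vis–NIR hyperspectral chemometrics for monitoring lipid oxidation in
packaged raw meat.

## The problem

Malondialdehyde (MDA, mg/100 g) is the standard secondary lipid-oxidation
marker of meat freshness: raw beef stored unpackaged at 4 °C typically
crosses the 0.15 mg/100 g spoilage threshold around storage day 4, while
vacuum PE-packed beef stays below it for a week. Hyperspectral imaging
(400–1000 nm, 125 bands) can predict MDA non-destructively from the
reflectance spectrum of each sample — but a packaging film attenuates the
signal, suppresses the 560 nm myoglobin feature, and superimposes
high-frequency "spurious peak" interference that degrades calibration
models. `oxispec` implements the full analysis chain and the 1-D spectral
de-interference filtering that recovers much of the lost accuracy, for
researchers in food-quality NIR spectroscopy and chemometrics.

## What is in the box

* **Hypercube I/O and ROI extraction** — ENVI-style cubes, black/white
  reflectance calibration `I = (R − R₁)/(R₂ − R₁)`, band-difference
  thresholding with hole filling, mean ROI spectra
  (`oxispec.hypercube`, `oxispec.envi`).
* **Reference chemistry** — TBARS standard-curve fit and
  `X [mg/kg] = c·V/m` content arithmetic (`oxispec.chemistry`).
* **Synthetic storage study** — a generator that emulates the two-group
  (blank vs. PE-packed) 7-day experiment, with absorption features at
  560/610/739/760/810/960 nm, MDA-linked dip depths at 610 and 760 nm and
  a parametric film-artifact model (`oxispec.simulate`).
* **Pretreatments** — SNV, min-max normalization, baseline offset,
  detrend, Savitzky–Golay, MSC, OSC as scikit-learn transformers
  (`oxispec.preprocess`).
* **De-interference filters** — Gaussian, median and FIR 1-D filters with
  explicit edge policies (`oxispec.filters`).
* **Partitioning** — Monte-Carlo PLS outlier screening and SPXY
  (joint x–y Kennard–Stone) splitting; 153 samples at 3:1 give the
  canonical 114/39 (`oxispec.partition`).
* **Wavelength selection** — CARS, iVISSA and VCPA around a fast SIMPLS
  PLS core with shared cross-validation folds (`oxispec.selection`,
  `oxispec.pls`).
* **Models** — PLSR (SIMPLS) and an echo state network whose
  hyperparameters are tuned by the bald eagle search metaheuristic
  (`oxispec.esn`, `oxispec.bes`, `oxispec.models`).
* **Visualization** — pixel-wise MDA prediction maps with a shared linear
  jet color scale (`oxispec.mapping`).
* **Orchestration** — `RunConfig`/`run_pipeline` manifests and an
  `oxispec` CLI (`simulate`, `ingest`, `partition`, `train`, `evaluate`,
  `map`, `grid`).

All estimators follow scikit-learn conventions (`fit`/`predict`/
`transform`, fitted attributes with trailing underscores) and compose with
`sklearn.pipeline.Pipeline`; calibration-only fitting of every stateful
step (MSC reference, OSC basis, selected bands, hyperparameters) is
asserted by the test suite.

## Worked example

```python
from oxispec import FilterSpec, RunConfig
from oxispec.pipeline import run_grid

configs = [
    RunConfig(group="blank", model="plsr", seed=5),
    RunConfig(group="pe_packed", model="plsr", seed=5),
    RunConfig(group="pe_packed", filter_spec=FilterSpec("gaussian"),
              model="plsr", seed=5),
    RunConfig(group="pe_packed", model="bes_esn",
              model_params=dict(population=6, iterations=6, cv_folds=3),
              seed=5),
]
print(run_grid(configs).round(4).to_string(index=False))
```

which prints:

```
                              label   R2_C  RMSEC   R2_P  RMSEP     RPD  n_variables  LVs
       blank-nofilter-raw-full-plsr 0.9990 0.0032 0.9985 0.0038 25.9980          125  3.0
   pe_packed-nofilter-raw-full-plsr 0.8583 0.0094 0.5312 0.0126  1.4748          125  6.0
   pe_packed-gaussian-raw-full-plsr 0.7720 0.0119 0.5900 0.0118  1.5769          125  3.0
pe_packed-nofilter-raw-full-bes_esn 0.7896 0.0114 0.5907 0.0118  1.5784          125  NaN
```

Read: unpackaged spectra predict MDA almost perfectly (R²_P ≈ 1.0), while
packaging-film interference collapses PLSR to R²_P ≈ 0.53. Gaussian
filtering recovers part of the loss (≈ 0.59), and the BES-tuned echo
state network reaches the same level without any filtering — its leaky
state integration low-passes the interference intrinsically. Individual
seeds vary; the systematic versions of these comparisons (20 seeds, sign
tests) run in `tests/test_acceptance.py`.

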