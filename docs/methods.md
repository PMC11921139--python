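# Methods

## Scope and shape

`oxispec` models malondialdehyde (MDA) content of raw beef from Vis–NIR
reflectance spectra (125 bands, 400–1000 nm) and corrects the spectral
interference of a PE packaging film by 1-D filtering before modeling. The
package is organised as scikit-learn estimators so that filter →
pretreatment → band selection → regressor chains are ordinary
`sklearn.pipeline.Pipeline` objects: every stateful step learns its state
(`reference_`, `weights_`, `selected_`, hyperparameters) from calibration
rows only and applies it frozen to validation rows and to pixels at map
time.

The instrument's stated band grid is internally inconsistent (125 bands
over 400–1000 nm is a 4.84 nm pitch, which matches neither a 1.5 nm
sampling spacing nor a 5.8 nm resolution); the package assumes a linear
125-point grid on [400, 1000] nm and exposes it as configuration.

## Reference chemistry

The TBARS assay's arithmetic: a linear standard curve A = slope·c +
intercept (OLS) maps absorbance to concentration c (µg/mL), and content is
X [mg/kg] = c·V/m with extract volume V (mL) over specimen mass m (g);
mg/100 g = X/10. The widely printed "×1000 ×1000" factors cancel exactly
under these units (1 µg/g = 1 mg/kg), so they are not applied.

## Synthetic storage study

No public dataset exists for this design, so a generator emulates the
experiment's statistical structure; its defaults are the study conditions
all acceptance properties are evaluated under.

* **Design**: 2 groups × 7 days × 30 samples/day (420 samples).
* **MDA trajectories** (mg/100 g): blank group
  `0.02 + 0.28/(1 + exp(−1.1(d − 3.5)))` (crosses the 0.15 spoilage
  threshold between day 3 and day 4, asymptote 0.30), noise sd 0.02;
  PE-packed group `0.06 + 0.01(d − 1)` (never crosses), noise sd 0.015;
  draws truncated at 0.
* **Clean spectra**: sigmoidal baseline 0.30 → 0.55 across the visible–NIR
  plus a small per-day shift (reflectance falls through day 6, rebounds
  day 7), minus truncated-Gaussian absorption dips (sd 12 nm) at 560
  (0.06), 610, 739 (0.04), 760, 810 (0.02) and 960 nm (0.05). The 610 and
  760 nm dips deepen by `0.3 × MDA` — the MDA signal is therefore exactly
  affine in the dip depths, and OLS of MDA on continuum-referenced depths
  has R² = 1 with noise off (≈ 0.99 at default noise). Per-sample
  multiplicative scatter (sd 0.006), additive offset (sd 0.003) and white
  band noise (sd 0.003) emulate instrument effects; noisy draws are
  clipped to [0.25, 0.60].
* **Film artifacts**: multiplicative attenuation 0.78 (overall packed
  reflectance < 0.5), 85% suppression of the fixed 560 nm myoglobin dip,
  two sinusoidal interference components of amplitude 0.018 whose periods
  are drawn per sample from 8 ± 25% bands (random phases), plus extra
  band noise sd 0.010. The per-sample period draw matters: a fixed-period
  ripple spans only the 2-D sin/cos subspace, which any linear calibration
  projects out; drawn periods spread the interference over many
  directions, so only smoothing can remove it — that is the mechanism by
  which filtering helps and film hurts, and its strength was calibrated so
  that packed-raw PLSR degrades to the reported R²_P ≈ 0.6 class while
  unpacked models stay high.
* **Cubes**: an elliptical foreground carrying the sample spectrum (plus
  optional pixel noise and a left–right MDA gradient) over a 0.05
  reflectance pedestal. With the default 810 nm − 450 nm band difference
  the foreground contrast is ≈ 0.22, so the 0.2 ROI threshold separates
  unpacked cubes; film attenuation scales the difference below 0.2, so
  packed-cube demonstrations pass `threshold=0.15`.

What the generator does **not** emulate: illumination geometry, specular
highlights, scan-stripe artifacts, myoglobin redox chemistry, nonlinear
MDA–spectrum links, and day-correlated spectral confounders beyond the
small baseline shift. Passing tests therefore show that the pipeline
recovers a planted, essentially linear signal under realistic noise and
structured interference — not that it would achieve the same accuracy on
real beef.

## Partitioning

Monte-Carlo outlier screening fits PLSR on random 75% subsets (500 rounds)
and accumulates out-of-sample residuals per sample; samples whose residual
mean or spread exceeds 3 robust z-scores (median/MAD, OR rule) are
rejected. A scale floor of 1e-6 × sd(y) prevents spurious flags when
residuals are numerically zero. SPXY then splits 3:1 by greedy max-min
selection on d = dx/max(dx) + dy/max(dy) (Euclidean in x, absolute in y),
seeded with the most distant pair, ties to the smallest index, calibration
count = floor(0.75 n). The y-extremes land in calibration up to near-ties
of the joint distance (asserted to 2% of the y-range).

## Pretreatments and filters

SNV, min-max normalization ("Normalize" is not defined by convention, so
min-max was chosen with area/unit-norm easy to add), baseline-minimum
subtraction, polynomial detrend (default order 2), Savitzky–Golay
(11/2, `mode="interp"` edges), MSC against the frozen calibration-mean
reference, and Wold-style OSC (default 1 component; removed scores are
orthogonalized against y to |tᵀy| ≤ 1e-8‖t‖‖y‖).

Filters and edge policies: Gaussian (σ = 2 bands, radius 3σ, window
weights renormalized at the edges), median (K = 2, edge replication), FIR
(causal, zero initial conditions; 21-tap Hamming windowed-sinc, cutoff
0.15 cycles/band, unit DC gain). Defaults attenuate interference of
period ≈ 8 bands while the ≈ 6-band-wide absorption dips survive; the FIR
group delay of 10 bands is harmless to the models (a pure band
relabeling) but is compensated when filter residuals are compared
directly. Filters are applied before pretreatments.

## PLSR and wavelength selection

The PLS1 core is SIMPLS, returning coefficients for every LV count
1..max_lv from one fit; LV is chosen at the first RMSECV minimum.
Cross-validation folds are seeded once per run and shared by all selectors
so RMSECV values are comparable. For univariate y SIMPLS coincides with
NIPALS; the scikit-learn implementation is used as an independent oracle
in the tests.

* **CARS** (defaults: 500 runs, 80% Monte-Carlo sampling, centering,
  max 20 LV, 20-fold CV): per run the retained set is scored by RMSECV,
  then a PLS fit on a random sample subset ranks bands by |coefficient|;
  the forced schedule rᵢ = b·(b/2)^(−(i−1)/(N−1)) (b → 2) truncates, and
  adaptive reweighted sampling (draws proportional to |coefficient|,
  de-duplicated) competes the rest. The minimal-RMSECV subset wins.
* **iVISSA** (weighted binary matrix sampling; the literature variant is
  under-specified, so the implemented reading is documented here): n_bms
  draws per iteration with per-band inclusion weights (init 0.5), weights
  updated to each band's frequency among the best 10% of draws; after the
  global iterations, bands with weight ≥ 0.5 are kept and a local stage
  greedily widens them into contiguous intervals while RMSECV does not
  worsen.
* **VCPA** (defaults: BMS 1000, 50 EDF rounds, max 10 LV): inclusion
  probability 0.5 over a surviving pool that a strictly decreasing EDF
  schedule shrinks to 14 bands (ranked by frequency among the best 10%);
  the final answer is an exhaustive search over all non-empty combinations
  of the survivors with a one-standard-error parsimony rule: among subsets
  whose RMSECV lies within one fold-level SE of the minimum, the smallest
  wins (a plain argmin over ~2¹⁰–2¹⁴ candidates systematically rewards
  chance supersets; the strict argmin is retained in the result's extras).

Tests and the acceptance suite run these at reduced budgets (e.g. CARS
150 runs/5 folds, VCPA 200 draws/20 rounds/pool 10) — the package's
desk-scale working sizes; code defaults remain the full budgets.

## ESN and BES

The echo state network treats the wavelength axis as the sequence axis:
s[t+1] = (1−a)s[t] + a·tanh(W_in u[t] + W s[t]), recurrent matrix W sparse
(10% nonzero) and rescaled to spectral radius < 1, so initial conditions
fade. Inputs are centered on the calibration mean spectrum so the
reservoir responds to reflectance variation rather than the constant
pedestal. The readout is ridge regression (dual form when features
outnumber samples) on the state trajectory subsampled every 4 bands after
a 4-band washout, concatenated with the centered input itself (a direct
input–output connection). A final-state-only readout was tried first and
discarded: it compresses the whole spectrum into one reservoir state and
loses the band-local information the MDA dips carry, leaving the ESN
systematically behind PLSR; trajectory readouts with a direct connection
are standard reservoir-computing practice and make the comparison fair.
The leaky integration acts as a tunable low-pass along wavelength, which
is precisely why the ESN tolerates film interference that PLSR cannot
project out.

Bald eagle search (select → spiral search → swoop, greedy per-candidate
acceptance, so the best value is monotone) tunes reservoir size [30, 150],
spectral radius [0.3, 0.98], input scaling [0.5, 20], leak rate [0.1, 1]
and log₁₀ ridge [−6, 2] against K-fold CV RMSE; the ESN's internal seed is
fixed during the search so candidates are comparable, and the final model
is refit on all calibration rows at the optimum. Default search budget in
the acceptance suite: population 6, 6 iterations, 3 folds.

## Metrics and maps

R² = 1 − SS_res/SS_tot (about the reference mean — not a squared
correlation), RMSE = √(SS_res/n), RPD = sd(reference, ddof 1)/RMSEP.
Prediction maps pass every foreground pixel through the frozen chain;
color is a linear jet scale with anchors defaulting to the 1st–99th
percentile of the rendered panel (shared across a multi-day panel so
color drift reflects MDA), background painted dark blue; PNG output is
byte-deterministic and the value grid is exported alongside for testing
without image decoding.

## Numerical choices and degenerate inputs

Zero-variance rows are rejected by SNV/normalize with the row index named;
MSC slopes below 1e-12 are errors; SIMPLS stops early when the residual
covariance collapses (remaining LV columns repeat the converged solution);
RMSECV LV counts are capped at fold-train size − 1; ties in selector
rankings, max-min selection and argmin traces all break toward the
smallest index for reproducibility; one global seed fans out to stage
seeds via `stage_seed(seed, stage) = (1009·seed + offset) mod 2³¹`.

## Known limitations

The generator's MDA–spectrum link is affine by construction, so linear
models are near-optimal on unpacked data and the ESN's advantage appears
only under film interference. Real packaging interference is richer than
two random-period sinusoids plus noise; filter rankings could differ on
real data. iVISSA follows one defensible reading of an under-specified
method. The SPXY y-containment and the packed-cube ROI threshold hold
only to the tolerances stated above.
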