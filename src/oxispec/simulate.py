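"""Synthetic Vis-NIR beef-spectra generator.

The reference dataset (125-band reflectance of raw beef stored 1-7 days,
30 samples/day in each of two groups, with wet-chemistry MDA values) is not
publicly deposited, so this module generates data with the same statistical
structure, making every downstream stage testable:

* MDA trajectories: the non-packaged ("blank") group rises logistically and
  crosses the 0.15 mg/100 g spoilage threshold between day 3 and day 4; the
  vacuum PE-packed group rises slowly and linearly, staying below the
  threshold for the whole week.
* Clean spectra: a smooth sigmoidal baseline within the 0.3-0.55 reflectance
  range with Gaussian absorption dips at 560, 610, 739, 760, 810 and 960 nm.
  The dips at 610 and 760 nm deepen affinely with MDA (configurable link
  strength) so the signal is linearly recoverable — the floor that makes
  model-acceptance checks meaningful.
* Film effects: multiplicative attenuation (overall reflectance drops below
  0.5), suppression of the 560 nm myoglobin dip, a random-phase sinusoidal
  ripple ("spurious peaks") and extra band noise.
* Cubes: a spatialized sample (elliptical foreground over a low-reflectance
  pedestal) whose ROI-extracted mean spectrum recovers the input spectrum.

All draws flow through an explicit numpy Generator, so a fixed seed gives
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypercube import DEFAULT_WAVELENGTHS_NM, Hypercube, MeanSpectrum

GROUPS = ("blank", "pe_packed")

#: Gaussian dip centres (nm) -> fixed depth; linked dips get extra depth
DIP_CENTERS_NM = (560.0, 610.0, 739.0, 760.0, 810.0, 960.0)
DIP_FIXED_DEPTH = {560.0: 0.06, 610.0: 0.02, 739.0: 0.04,
                   760.0: 0.02, 810.0: 0.02, 960.0: 0.05}
MDA_LINKED_NM = (610.0, 760.0)
DIP_SD_NM = 12.0

#: per-day additive reflectance shift: darkening through day 6, rebound day 7
DAY_SHIFT = (0.0, -0.004, -0.008, -0.012, -0.016, -0.020, -0.010)

MDA_NOISE_SD = {"blank": 0.02, "pe_packed": 0.015}


@dataclass
class FilmParams:
    """PE packaging-film spectral artifact model.

    attenuation: multiplicative reflectance loss (scalar or per-band).
    peak560_suppression: fraction of the fixed 560 nm dip blended flat.
    ripple_amplitude / ripple_period_bands / period_jitter / n_ripple:
    "spurious peak" interference — ``n_ripple`` sinusoids per sample, each
    with amplitude ``ripple_amplitude``, random phase and a period drawn
    uniformly within ``ripple_period_bands * (1 +/- period_jitter)``.  The
    per-sample period draw makes the interference span many directions, so
    no linear projection can remove it, only smoothing can.
    noise_sd: extra band-wise white noise introduced by the film.
    """

    attenuation: float = 0.78
    peak560_suppression: float = 0.85
    ripple_amplitude: float = 0.018
    ripple_period_bands: float = 8.0
    period_jitter: float = 0.25
    n_ripple: int = 2
    noise_sd: float = 0.010


@dataclass
class GeneratorConfig:
    n_days: int = 7
    samples_per_day_per_group: int = 30
    seed: int = 0
    film: FilmParams = field(default_factory=FilmParams)
    noise_sd: float = 0.003          # white spectral noise
    scatter_sd: float = 0.006        # per-sample multiplicative scatter
    offset_sd: float = 0.003         # per-sample additive offset
    cube_size: tuple[int, int] = (32, 32)
    mda_link_strength: float = 0.3   # dip-depth increase per (mg/100 g)

    def __post_init__(self):
        if self.n_days < 1 or self.samples_per_day_per_group < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def expected_mda(day: int, group: str) -> float:
    """Noise-free mean of the MDA trajectory (mg/100 g)."""
    if group == "blank":
        return 0.02 + 0.28 / (1.0 + np.exp(-1.1 * (day - 3.5)))
    if group == "pe_packed":
        return 0.06 + 0.01 * (day - 1)
    raise ValueError(f"unknown group {group!r}")


def simulate_mda(day: int, group: str, rng: np.random.Generator,
                 noise_sd: float | None = None) -> float:
    """One MDA reference value (mg/100 g), truncated at zero."""
    mean = expected_mda(day, group)       # validates group
    if noise_sd is None:
        noise_sd = MDA_NOISE_SD[group]
    return float(max(0.0, mean + noise_sd * rng.standard_normal()))


def _dip_profile(wavelengths: np.ndarray, center: float,
                 sd: float = DIP_SD_NM) -> np.ndarray:
    """Truncated Gaussian dip shape (exactly zero beyond 4 sd)."""
    d = wavelengths - center
    prof = np.exp(-(d * d) / (2.0 * sd * sd))
    prof[np.abs(d) >= 4.0 * sd] = 0.0
    return prof


def baseline_template(wavelengths: np.ndarray, day: int = 1) -> np.ndarray:
    """Smooth sigmoidal reflectance baseline with a small storage-day shift."""
    base = 0.30 + 0.248 / (1.0 + np.exp(-(wavelengths - 600.0) / 50.0))
    return base + DAY_SHIFT[min(int(day), len(DAY_SHIFT)) - 1]


def clean_spectrum_template(mda: float, day: int = 1,
                            link_strength: float = 0.3,
                            wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Deterministic baseline-minus-dips spectrum for a given MDA level."""
    if mda < 0:
        raise ValueError("mda must be non-negative")
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    spec = baseline_template(wl, day).copy()
    for c in DIP_CENTERS_NM:
        depth = DIP_FIXED_DEPTH[c]
        if c in MDA_LINKED_NM:
            depth = depth + link_strength * mda
        spec -= depth * _dip_profile(wl, c)
    return spec


def simulate_clean_spectrum(mda: float, day: int, rng: np.random.Generator | None = None,
                            link_strength: float = 0.3, noise_sd: float = 0.0,
                            scatter_sd: float = 0.0, offset_sd: float = 0.0,
                            wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Clean (film-free) spectrum; optional scatter/offset/white noise.

    With all noise terms zero the result equals
    :func:`clean_spectrum_template` exactly.  Noisy draws are clipped to the
    [0.25, 0.60] physical band.
    """
    spec = clean_spectrum_template(mda, day, link_strength, wavelengths)
    if noise_sd == 0.0 and scatter_sd == 0.0 and offset_sd == 0.0:
        return spec
    if rng is None:
        raise ValueError("rng required when noise is enabled")
    a = 1.0 + scatter_sd * rng.standard_normal()
    b = offset_sd * rng.standard_normal()
    noisy = a * spec + b + noise_sd * rng.standard_normal(spec.shape)
    return np.clip(noisy, 0.25, 0.60)


def apply_film_effect(spectrum: np.ndarray, film: FilmParams,
                      rng: np.random.Generator | None = None,
                      wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Superimpose packaging-film artifacts on a clean spectrum.

    filmed = attenuation * (spectrum + suppression * dip560) + ripple + noise.
    The 560 nm term adds back (part of) the fixed myoglobin dip, emulating
    its disappearance under film.  Ripple phase is random per call; with
    attenuation 1, suppression 0 and zero ripple/noise this is the identity.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    out = spectrum + film.peak560_suppression * DIP_FIXED_DEPTH[560.0] * \
        _dip_profile(wl, 560.0)
    out = film.attenuation * out
    if film.ripple_amplitude != 0.0:
        if rng is None:
            raise ValueError("rng required for ripple phase")
        idx = np.arange(wl.size)
        for _ in range(film.n_ripple):
            period = film.ripple_period_bands * (
                1.0 + film.period_jitter * rng.uniform(-1.0, 1.0))
            phase = rng.uniform(0, 2 * np.pi)
            out = out + film.ripple_amplitude * np.sin(
                2 * np.pi * idx / period + phase)
    if film.noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required for film noise")
        out = out + film.noise_sd * rng.standard_normal(out.shape)
    return out


def _ellipse_mask(rows: int, cols: int, margin: int = 2) -> np.ndarray:
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    ry, rx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = ry - margin, rx - margin
    return ((r - ry) / max(ay, 0.5)) ** 2 + ((c - rx) / max(ax, 0.5)) ** 2 <= 1.0


def build_cube(spectrum: np.ndarray, cube_size: tuple[int, int] = (32, 32),
               rng: np.random.Generator | None = None, noise_sd: float = 0.005,
               background: float = 0.05,
               wavelengths: np.ndarray | None = None) -> tuple[Hypercube, np.ndarray]:
    """Spatialize one sample spectrum into a cube; returns (cube, true mask).

    Foreground pixels carry the spectrum plus optional i.i.d. pixel noise;
    the background is a flat low-reflectance pedestal.
    """
    rows, cols = cube_size
    if rows < 4 or cols < 4:
        raise ValueError("cube must be at least 4x4 pixels")
    spectrum = np.asarray(spectrum, dtype=np.float64)
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    fg = _ellipse_mask(rows, cols)
    data = np.full((rows, cols, spectrum.size), background)
    data[fg] = spectrum
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for pixel noise")
        data[fg] += noise_sd * rng.standard_normal((int(fg.sum()), spectrum.size))
    return Hypercube(data, wl), fg


def build_gradient_cube(mda: float, day: int = 1,
                        cube_size: tuple[int, int] = (32, 32),
                        rng: np.random.Generator | None = None,
                        gradient: float = 0.5, link_strength: float = 0.3,
                        noise_sd: float = 0.003, background: float = 0.05,
                        film: FilmParams | None = None) -> tuple[Hypercube, np.ndarray, np.ndarray]:
    """Cube with a smooth left-to-right MDA gradient across the foreground.

    Column c carries MDA ``mda * (1 + gradient * (c_norm - 0.5))``.  Returns
    (cube, mask, per-column MDA).  Used for visualization-map checks.
    """
    rows, cols = cube_size
    if rows < 4 or cols < 4:
        raise ValueError("cube must be at least 4x4 pixels")
    wl = DEFAULT_WAVELENGTHS_NM
    col_norm = np.arange(cols) / max(cols - 1, 1)
    col_mda = mda * (1.0 + gradient * (col_norm - 0.5))
    fg = _ellipse_mask(rows, cols)
    data = np.full((rows, cols, wl.size), background)
    for c in range(cols):
        spec = clean_spectrum_template(max(col_mda[c], 0.0), day, link_strength, wl)
        if film is not None:
            spec = apply_film_effect(spec, film, rng, wl)
        data[:, c, :][fg[:, c]] = spec
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for pixel noise")
        data[fg] += noise_sd * rng.standard_normal((int(fg.sum()), wl.size))
    return Hypercube(data, wl), fg, col_mda


@dataclass
class SpectraDataset:
    """n x b spectra with aligned MDA truth and experimental labels."""

    x: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    days: np.ndarray
    ids: np.ndarray
    wavelengths_nm: np.ndarray

    def subset(self, group: str) -> "SpectraDataset":
        m = self.groups == group
        return SpectraDataset(self.x[m], self.y[m], self.groups[m],
                              self.days[m], self.ids[m], self.wavelengths_nm)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.ids, "group": self.groups,
                             "day": self.days, "mda_mg_per_100g": self.y})

    def to_mean_spectra(self) -> list[MeanSpectrum]:
        return [MeanSpectrum(values=self.x[i], sample_id=str(self.ids[i]),
                             group=str(self.groups[i]), day=int(self.days[i]),
                             mda=float(self.y[i]))
                for i in range(len(self.y))]


def generate_dataset(config: GeneratorConfig | None = None) -> SpectraDataset:
    """Full two-group storage study: n_days x samples/day x {blank, pe_packed}.

    Blank-group spectra are clean + noise; PE-group spectra additionally
    pass through the film-effect model.  Deterministic under config.seed.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = DEFAULT_WAVELENGTHS_NM
    rows_x, rows_y, groups, days, ids = [], [], [], [], []
    for group in GROUPS:
        for day in range(1, cfg.n_days + 1):
            for i in range(cfg.samples_per_day_per_group):
                mda = simulate_mda(day, group, rng)
                spec = simulate_clean_spectrum(
                    mda, day, rng, cfg.mda_link_strength,
                    cfg.noise_sd, cfg.scatter_sd, cfg.offset_sd, wl)
                if group == "pe_packed":
                    spec = apply_film_effect(spec, cfg.film, rng, wl)
                rows_x.append(spec)
                rows_y.append(mda)
                groups.append(group)
                days.append(day)
                ids.append(f"{group[:2]}-d{day}-{i:02d}")
    return SpectraDataset(np.array(rows_x), np.array(rows_y),
                          np.array(groups), np.array(days), np.array(ids), wl)


def measured_dip_depths(x: np.ndarray, wavelengths: np.ndarray | None = None,
                        centers=MDA_LINKED_NM, flank_bands: int = 5) -> np.ndarray:
    """Continuum-referenced depths of the MDA-linked dips, per spectrum.

    Depth = mean of the two flanking bands minus the centre band; affine in
    MDA by construction, so OLS of MDA on these depths has R^2 = 1 when
    noise is off.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    depths = np.empty((x.shape[0], len(centers)))
    for j, c in enumerate(centers):
        k = int(np.argmin(np.abs(wl - c)))
        lo, hi = max(k - flank_bands, 0), min(k + flank_bands, wl.size - 1)
        depths[:, j] = 0.5 * (x[:, lo] + x[:, hi]) - x[:, k]
    return depths


def make_planted_regression(n_samples: int = 60, n_bands: int = 125,
                            n_planted: int = 5, noise_sd: float = 0.05,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regression fixture with a known active-band set for selector checks.

    X is i.i.d. standard normal; y is a linear combination of ``n_planted``
    evenly spread bands (unit-ish weights) plus Gaussian noise.  Returns
    (x, y, planted_indices).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_samples, n_bands))
    planted = np.linspace(0, n_bands - 1, n_planted + 2)[1:-1].round().astype(int)
    w = 1.0 + 0.2 * np.arange(n_planted)
    y = x[:, planted] @ w + noise_sd * rng.standard_normal(n_samples)
    return x, y, planted
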