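"""Hypercube container, black/white reflectance calibration and ROI extraction.

A hypercube is a (rows, cols, bands) reflectance grid with a strictly
increasing wavelength axis.  Raw camera counts are converted to reflectance
with the dark/white reference correction

    I = (R - R_dark) / (R_white - R_dark),

stored as a fraction (the percent form is presentation only).  The region
of interest (the meat surface) is segmented by thresholding the difference
between a high-reflectance NIR band image and a low-reflectance visible
band image, filling interior holes, and the sample's spectrum is the
per-band mean over foreground pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import binary_fill_holes

#: default wavelength axis: 125 bands linearly spaced on 400-1000 nm
DEFAULT_WAVELENGTHS_NM = np.linspace(400.0, 1000.0, 125)

#: default ROI band-difference wavelengths (high NIR minus low visible)
DEFAULT_HIGH_NM = 810.0
DEFAULT_LOW_NM = 450.0


class CalibrationError(ValueError):
    """Dark/white correction is ill-posed (zero-denominator voxels)."""


class DegenerateRoiError(ValueError):
    """Thresholding produced an empty foreground; the sample is rejected."""


@dataclass
class Hypercube:
    """Reflectance grid (rows x cols x bands) with its wavelength axis."""

    data: np.ndarray
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: DEFAULT_WAVELENGTHS_NM.copy())
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (rows, cols, bands)")
        if self.wavelengths_nm.shape[0] != self.data.shape[2]:
            raise ValueError("wavelength axis length must equal band count")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("hypercube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_nearest(self, wavelength_nm: float) -> int:
        """Index of the band closest to a wavelength."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


@dataclass
class RoiMask:
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class MeanSpectrum:
    """Mean ROI spectrum of one sample plus its experimental labels."""

    values: np.ndarray
    sample_id: str = ""
    group: str = "blank"
    day: int = 1
    mda: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mean spectrum contains non-finite values")
        if self.group not in {"blank", "pe_packed"}:
            raise ValueError(f"group must be 'blank' or 'pe_packed', got {self.group!r}")
        if not 1 <= int(self.day) <= 7:
            raise ValueError("storage day must be in [1, 7]")


def black_white_correct(raw, dark, white, wavelengths_nm=None,
                        meta: dict | None = None) -> Hypercube:
    """Dark/white reflectance calibration I = (R - R1) / (R2 - R1)."""
    raw = np.asarray(raw, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    white = np.asarray(white, dtype=np.float64)
    if not (raw.shape == dark.shape == white.shape):
        raise ValueError(
            f"raw/dark/white shapes differ: {raw.shape}, {dark.shape}, {white.shape}")
    denom = white - dark
    n_zero = int(np.count_nonzero(denom == 0))
    if n_zero:
        raise CalibrationError(
            f"white minus dark is zero at {n_zero} voxel(s); cannot calibrate")
    if wavelengths_nm is None:
        if raw.shape[2] == DEFAULT_WAVELENGTHS_NM.size:
            wavelengths_nm = DEFAULT_WAVELENGTHS_NM.copy()
        else:
            wavelengths_nm = np.linspace(400.0, 1000.0, raw.shape[2])
    return Hypercube((raw - dark) / denom, wavelengths_nm, meta or {})


def band_difference_image(cube: Hypercube, high_band: int, low_band: int) -> np.ndarray:
    """Per-pixel difference of two band images (may be negative)."""
    bands = cube.shape[2]
    for idx in (high_band, low_band):
        if not 0 <= idx < bands:
            raise IndexError(f"band index {idx} out of range [0, {bands})")
    return cube.data[:, :, high_band] - cube.data[:, :, low_band]


def threshold_mask(image, threshold: float = 0.2, fill_holes: bool = True) -> RoiMask:
    """Binarize at ``image > threshold``; optionally fill interior holes.

    Hole filling treats background pixels unreachable from the image border
    (4-connectivity) as foreground, eliminating speckle inside the sample.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("threshold image must be finite")
    mask = image > threshold
    if fill_holes:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        mask = binary_fill_holes(mask, structure=structure)
    if not mask.any():
        raise DegenerateRoiError(
            f"no pixel exceeds threshold {threshold}; sample rejected")
    return RoiMask(mask)


def mean_spectrum(cube: Hypercube, mask: RoiMask, **labels) -> MeanSpectrum:
    """Per-band arithmetic mean over foreground pixels."""
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match cube spatial shape")
    if mask.n_foreground == 0:
        raise DegenerateRoiError("empty ROI mask")
    values = cube.data[mask.mask].mean(axis=0)
    return MeanSpectrum(values=values, **labels)


def default_roi_pipeline(cube: Hypercube, threshold: float = 0.2,
                         high_nm: float = DEFAULT_HIGH_NM,
                         low_nm: float = DEFAULT_LOW_NM, **labels) -> MeanSpectrum:
    """Band difference -> threshold -> hole fill -> mean spectrum."""
    diff = band_difference_image(cube, cube.band_nearest(high_nm),
                                 cube.band_nearest(low_nm))
    mask = threshold_mask(diff, threshold=threshold)
    return mean_spectrum(cube, mask, **labels)
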