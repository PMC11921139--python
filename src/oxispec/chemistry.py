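"""Wet-chemistry MDA reference arithmetic (TBARS assay).

The spectrophotometric assay reads an absorbance, converts it to an MDA
concentration through a linear standard curve, and scales by extract volume
over specimen mass:

    c [ug/mL] = (A - intercept) / slope
    X [mg/kg] = c * V[mL] / m[g]        (1 ug/g == 1 mg/kg)

Results are also reported in mg/100 g (X / 10), the unit used for the
0.15 mg/100 g spoilage threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class CurveFitError(ValueError):
    """Degenerate standard-curve design (too few or identical concentrations)."""


@dataclass
class StandardCurve:
    slope: float          # absorbance per (ug/mL)
    intercept: float      # absorbance
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


@dataclass
class AssayRecord:
    absorbance: float
    volume_ml: float
    mass_g: float

    def __post_init__(self):
        if self.volume_ml <= 0 or self.mass_g <= 0:
            raise ValueError("volume and mass must be positive")


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Ordinary least-squares line A = slope*c + intercept."""
    c = np.asarray(concentrations, dtype=np.float64)
    a = np.asarray(absorbances, dtype=np.float64)
    if c.size < 3 or c.size != a.size:
        raise CurveFitError("need at least 3 paired standard points")
    if np.ptp(c) == 0:
        raise CurveFitError("all standard concentrations identical")
    res = stats.linregress(c, a)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def mda_content(curve: StandardCurve, record: AssayRecord) -> dict[str, float]:
    """MDA content from one assay record; keys ``mg_per_kg`` / ``mg_per_100g``.

    Absorbance below the intercept clips concentration at zero.
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    c = max(0.0, (record.absorbance - curve.intercept) / curve.slope)  # ug/mL
    x_mg_kg = c * record.volume_ml / record.mass_g
    return {"mg_per_kg": x_mg_kg, "mg_per_100g": x_mg_kg / 10.0}
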