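"""Pixel-wise MDA prediction maps.

Every foreground pixel's spectrum is passed through the *frozen* transform
chain and model fitted on the calibration set, producing a map of predicted
MDA (mg/100 g).  Maps are rendered with a linear jet-style color scale —
blue is fresh, red is oxidized — with the background painted dark blue.
Scale anchors can be shared across a multi-day panel so color drift between
days reflects MDA, not rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib import cm, colors  # noqa: E402

from .hypercube import Hypercube, RoiMask  # noqa: E402

BACKGROUND_RGBA = (0.0, 0.0, 0.35, 1.0)  # dark blue


@dataclass
class PredictionMap:
    """Predicted MDA per pixel; NaN marks background."""

    values: np.ndarray
    scale_min: float
    scale_max: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        fg = self.values[np.isfinite(self.values)]
        if fg.size == 0:
            raise ValueError("prediction map has no foreground")
        if not self.scale_min < self.scale_max:
            raise ValueError("scale_min must be below scale_max")

    def foreground_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def pixelwise_predict(cube: Hypercube, mask: RoiMask, pipeline,
                      scale: tuple[float, float] | None = None) -> PredictionMap:
    """Predict MDA at every foreground pixel with a fitted pipeline.

    ``pipeline`` is any fitted object with ``predict`` (e.g. an sklearn
    Pipeline of filter/pretreatment/selector/model).  Background pixels
    stay NaN.  Default scale anchors: 1st-99th percentile of the predicted
    foreground.
    """
    if not hasattr(pipeline, "predict"):
        raise TypeError("pipeline must expose predict()")
    spectra = cube.data[mask.mask]
    if spectra.shape[0] == 0:
        raise ValueError("empty mask")
    pred = np.asarray(pipeline.predict(spectra), dtype=np.float64).ravel()
    values = np.full(mask.mask.shape, np.nan)
    values[mask.mask] = pred
    if scale is None:
        lo, hi = np.percentile(pred, [1, 99])
        if hi <= lo:
            hi = lo + 1e-9
        scale = (float(lo), float(hi))
    return PredictionMap(values=values, scale_min=scale[0], scale_max=scale[1])


def shared_scale(maps: list[PredictionMap]) -> tuple[float, float]:
    """1st-99th percentile anchors over a whole panel of maps."""
    allv = np.concatenate([m.foreground_values() for m in maps])
    lo, hi = np.percentile(allv, [1, 99])
    if hi <= lo:
        hi = lo + 1e-9
    return float(lo), float(hi)


def map_to_rgba(pmap: PredictionMap) -> np.ndarray:
    """Linear jet mapping of the value grid; background -> dark blue."""
    norm = colors.Normalize(vmin=pmap.scale_min, vmax=pmap.scale_max, clip=True)
    cmap = matplotlib.colormaps["jet"]
    rgba = cmap(norm(np.nan_to_num(pmap.values, nan=pmap.scale_min)))
    rgba[~np.isfinite(pmap.values)] = BACKGROUND_RGBA
    return rgba


def render_map(pmap: PredictionMap, out_path, title: str | None = None) -> None:
    """Write the map as a PNG with an embedded color bar.

    Output bytes are deterministic for fixed inputs (no timestamp metadata).
    """
    fig, ax = plt.subplots(figsize=(4, 3.2))
    rgba = map_to_rgba(pmap)
    ax.imshow(rgba, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    sm = cm.ScalarMappable(
        norm=colors.Normalize(pmap.scale_min, pmap.scale_max), cmap="jet")
    fig.colorbar(sm, ax=ax, label="MDA (mg/100 g)")
    fig.savefig(out_path, dpi=100, metadata={"Software": "oxispec"})
    plt.close(fig)
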