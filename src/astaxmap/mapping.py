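"""Pixel-wise astaxanthin concentration maps from a calibrated PLS model.

The regression vector of a PLS model fitted on ROI mean spectra can be
applied to every ROI pixel of a cube, yielding a spatial map of predicted
concentration.  Because the whole pipeline (autoscaling + regression) is
affine, the ROI mean of the pixel-wise map equals the scalar prediction of
the ROI mean spectrum — a useful internal consistency check.  Pixel-level
accuracy is *not* validated against chemistry; maps are for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .cube_model import DomainError, Mask, ShapeError, SpectralCube
from .chemometrics import PLSModel, predict

__all__ = ["ConcentrationMap", "predict_map", "render_map", "BLUE_RED"]

#: Blue (low) -> cyan -> yellow -> red (high) map used for concentration
#: rendering; endpoints are pure blue and pure red.
BLUE_RED = LinearSegmentedColormap.from_list(
    "astax_blue_red",
    [(0.0, 0.0, 1.0), (0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (1.0, 0.0, 0.0)],
)

#: Default display range in µg/g spanning the study's concentration range.
DEFAULT_RANGE = (0.0, 4.5)


@dataclass
class ConcentrationMap:
    """``H x W`` predicted concentration (µg/g); NaN outside the ROI."""

    data: np.ndarray
    roi: Mask
    units: str = "ug/g"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.roi.data.shape:
            raise ShapeError("map and roi shapes differ")

    @property
    def roi_values(self) -> np.ndarray:
        return self.data[self.roi.data]

    @property
    def roi_mean(self) -> float:
        return float(self.roi_values.mean())


def predict_map(
    cube: SpectralCube, roi: Mask, model: PLSModel
) -> ConcentrationMap:
    """Predict a per-pixel concentration map over the ROI.

    Each ROI pixel's spectrum is autoscaled with the model's *training*
    parameters and pushed through the regression vector; non-ROI pixels are
    NaN.
    """
    if cube.n_bands != model.n_features:
        raise ShapeError(
            f"cube has {cube.n_bands} bands, model expects {model.n_features}"
        )
    if roi.data.shape != cube.data.shape[:2]:
        raise ShapeError("roi shape does not match cube")
    if not roi.data.any():
        raise DomainError("roi is empty")
    out = np.full(cube.data.shape[:2], np.nan)
    out[roi.data] = predict(model, cube.data[roi.data])
    return ConcentrationMap(out, roi)


def render_map(
    cmap: ConcentrationMap,
    value_range: tuple[float, float] = DEFAULT_RANGE,
) -> np.ndarray:
    """Color-code a concentration map as an ``H x W x 4`` RGBA uint8 image.

    Values map linearly onto a blue (low) to red (high) colormap over
    ``value_range``; out-of-range values saturate at the endpoints.  Missing
    (non-ROI) pixels render neutral gray with zero alpha.
    """
    lo, hi = value_range
    if not lo < hi:
        raise DomainError("value range must be increasing")
    norm = (cmap.data - lo) / (hi - lo)
    norm = np.clip(norm, 0.0, 1.0)
    rgba = np.zeros(cmap.data.shape + (4,), dtype=np.uint8)
    valid = cmap.roi.data & np.isfinite(cmap.data)
    colors = BLUE_RED(norm[valid])  # n x 4 floats in [0, 1]
    rgba[valid] = np.round(colors * 255.0).astype(np.uint8)
    rgba[~valid] = (128, 128, 128, 0)
    return rgba


def write_map(cmap: ConcentrationMap, path: str | Path) -> Path:
    """Store map values as a 32-bit float TIFF (NaN outside the ROI)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, cmap.data.astype(np.float32))
    return path
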