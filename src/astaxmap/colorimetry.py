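"""CIE colorimetry: spectral reconstruction, XYZ integration and sRGB rendering.

To compare the 19-band calibration against an ordinary color-camera
baseline, each pixel's visible-band reflectances (the 12 bands between 395
and 700 nm) are interpolated to a dense 5 nm grid from 380 to 780 nm,
integrated against the CIE 1931 2-degree standard observer under a D65-like
illuminant, and converted to 8-bit sRGB.  Mean R, G, B over the ROI then
feed a 3-variable regression model.

The color-matching functions are generated from the published multi-lobe
Gaussian analytic fits of Wyman, Sloan & Shirley (2013), which approximate
the tabulated CIE 1931 observer to within about one percent.  The
illuminant is a 6504 K Planckian spectrum (a close stand-in for D65).  After
building the table, the x̄ and z̄ columns are rescaled once so the perfect
diffuser maps exactly to the nominal D65 white point (95.047, 100, 108.883)
— "white-point anchoring" — which makes every neutral-axis identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cube_model import BandSet, DomainError, Mask, ShapeError, SpectralCube

__all__ = [
    "ObserverTable",
    "D65_WHITE_XYZ",
    "reconstruct_spectrum",
    "spectrum_to_xyz",
    "xyz_to_srgb",
    "cube_to_rgb",
    "rgb_mean_features",
]

#: Nominal D65 white point on the Y=100 scale.
D65_WHITE_XYZ = np.array([95.047, 100.0, 108.883])

#: Linear XYZ (Y in [0,1]) -> linear sRGB matrix, D65 reference white.
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)

VISIBLE_UPPER_NM = 700.0


def _lobe(wl: np.ndarray, mu: float, s_lo: float, s_hi: float) -> np.ndarray:
    t = (wl - mu) * np.where(wl < mu, s_lo, s_hi)
    return np.exp(-0.5 * t * t)


def _cmf_1931(wl: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic multi-lobe fits to the CIE 1931 2-deg color-matching functions."""
    x = (
        0.362 * _lobe(wl, 442.0, 0.0624, 0.0374)
        + 1.056 * _lobe(wl, 599.8, 0.0264, 0.0323)
        - 0.065 * _lobe(wl, 501.1, 0.0490, 0.0382)
    )
    y = 0.821 * _lobe(wl, 568.8, 0.0213, 0.0247) + 0.286 * _lobe(
        wl, 530.9, 0.0613, 0.0322
    )
    z = 1.217 * _lobe(wl, 437.0, 0.0845, 0.0278) + 0.681 * _lobe(
        wl, 459.0, 0.0385, 0.0725
    )
    return np.clip(x, 0, None), np.clip(y, 0, None), np.clip(z, 0, None)


def _planckian(wl_nm: np.ndarray, t_kelvin: float = 6504.0) -> np.ndarray:
    """Relative Planckian spectral power, normalized to 100 at 560 nm."""
    c2 = 1.4388e-2  # m K
    wl_m = wl_nm * 1e-9
    s = wl_m**-5 / (np.exp(c2 / (wl_m * t_kelvin)) - 1.0)
    s560 = (560e-9) ** -5 / (np.exp(c2 / (560e-9 * t_kelvin)) - 1.0)
    return 100.0 * s / s560


@dataclass(frozen=True)
class ObserverTable:
    """CIE 1931 2-deg observer on a 5 nm grid with an illuminant SPD."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    illuminant: np.ndarray

    def __post_init__(self) -> None:
        n = self.wavelengths_nm.shape[0]
        for name in ("xbar", "ybar", "zbar", "illuminant"):
            if getattr(self, name).shape != (n,):
                raise ShapeError(f"{name} length must match wavelengths")
        if min(self.xbar.min(), self.ybar.min(), self.zbar.min()) < 0:
            raise DomainError("color-matching values must be non-negative")

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "ObserverTable":
        """81-row table on 380-780 nm, anchored to the D65 white point."""
        wl = np.arange(380.0, 781.0, 5.0)
        xb, yb, zb = _cmf_1931(wl)
        s = _planckian(wl)
        k = 100.0 / np.sum(s * yb)
        white_x = k * np.sum(s * xb)
        white_z = k * np.sum(s * zb)
        xb = xb * (D65_WHITE_XYZ[0] / white_x)
        zb = zb * (D65_WHITE_XYZ[2] / white_z)
        return cls(wl, xb, yb, zb, s)

    @property
    def n_rows(self) -> int:
        return self.wavelengths_nm.shape[0]


# ---------------------------------------------------------------------------
# Spectral reconstruction
# ---------------------------------------------------------------------------

def reconstruct_spectrum(
    bands: BandSet,
    values: np.ndarray,
    grid_nm: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate a dense 5 nm reflectance spectrum from the visible bands.

    Monotone piecewise-cubic (PCHIP) interpolation over the 12 visible band
    centers (395-700 nm), extended as a constant below 395 and above 700 nm,
    clipped to be non-negative.  ``values`` may be a single 19-vector or an
    ``(n, 19)`` stack; the result has one row per input spectrum.
    """
    if grid_nm is None:
        grid_nm = ObserverTable.default().wavelengths_nm
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    v2 = values[None, :] if single else values
    if v2.shape[1] != len(bands):
        raise ShapeError("values length must match the band set")
    if np.any(v2 < 0):
        raise DomainError("reflectance values must be non-negative")
    vis = bands.visible_indices(VISIBLE_UPPER_NM)
    if vis.size < 2:
        raise DomainError("need at least two visible bands")
    wl_vis = bands.array[vis]
    interp = PchipInterpolator(wl_vis, v2[:, vis].T, axis=0, extrapolate=True)
    clamped = np.clip(grid_nm, wl_vis[0], wl_vis[-1])  # constant extension
    dense = interp(clamped).T
    dense = np.clip(dense, 0.0, None)
    return dense[0] if single else dense


# ---------------------------------------------------------------------------
# XYZ and sRGB
# ---------------------------------------------------------------------------

def spectrum_to_xyz(
    reflectance: np.ndarray, obs: ObserverTable | None = None
) -> np.ndarray:
    """Integrate reflectance against the observer: X = k Σ R S x̄ Δλ, etc.

    ``k = 100 / Σ S ȳ Δλ`` so a perfect diffuser (R ≡ 1) has Y = 100.
    Accepts a single spectrum or an ``(n, 81)`` stack.
    """
    obs = obs or ObserverTable.default()
    r = np.asarray(reflectance, dtype=float)
    single = r.ndim == 1
    r2 = r[None, :] if single else r
    if r2.shape[1] != obs.n_rows:
        raise ShapeError("reflectance grid does not match observer table")
    s = obs.illuminant
    k = 100.0 / np.sum(s * obs.ybar)
    weights = np.stack([s * obs.xbar, s * obs.ybar, s * obs.zbar], axis=1)
    xyz = k * (r2 @ weights)
    return xyz[0] if single else xyz


def xyz_to_srgb(xyz: np.ndarray) -> np.ndarray:
    """XYZ (Y on the 0-100 scale) to 8-bit sRGB with gamma and clipping."""
    xyz = np.asarray(xyz, dtype=float)
    single = xyz.ndim == 1
    arr = xyz[None, :] if single else xyz
    if arr.shape[-1] != 3:
        raise ShapeError("xyz must have three components")
    linear = (arr / 100.0) @ _XYZ_TO_SRGB.T
    linear = np.clip(linear, 0.0, 1.0)
    low = linear <= 0.0031308
    encoded = np.where(
        low, 12.92 * linear, 1.055 * np.power(linear, 1.0 / 2.4) - 0.055
    )
    out = np.round(np.clip(encoded, 0.0, 1.0) * 255.0).astype(np.uint8)
    return out[0] if single else out


def cube_to_rgb(
    cube: SpectralCube, obs: ObserverTable | None = None
) -> np.ndarray:
    """Render a multispectral cube as an ``H x W x 3`` 8-bit sRGB image."""
    obs = obs or ObserverTable.default()
    h, w, _ = cube.shape
    flat = cube.data.reshape(-1, cube.n_bands)
    dense = reconstruct_spectrum(cube.bands, flat, obs.wavelengths_nm)
    xyz = spectrum_to_xyz(dense, obs)
    rgb = xyz_to_srgb(xyz)
    return rgb.reshape(h, w, 3)


def rgb_mean_features(
    rgb: np.ndarray, roi: Mask | np.ndarray
) -> np.ndarray:
    """Mean (R, G, B) over ROI pixels — the 3-variable baseline features."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ShapeError("rgb must be H x W x 3")
    m = roi.data if isinstance(roi, Mask) else np.asarray(roi, bool)
    if m.shape != rgb.shape[:2]:
        raise ShapeError("roi shape does not match image")
    if not m.any():
        raise DomainError("roi is empty")
    return rgb[m].astype(float).mean(axis=0)
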