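"""Core data types and file I/O for multispectral reflectance cubes.

A multispectral cube is an ``H x W x B`` stack of reflectance images, one
plane per narrow LED band.  The instrument emulated here (an integrating
sphere with 19 LEDs between 395 and 970 nm) records surface reflectance as a
dimensionless fraction; values slightly above 1 can occur on specular or very
bright surfaces and are allowed up to a nominal ceiling of 1.2.

Cubes are stored on disk as multi-page 16-bit grayscale TIFFs (one page per
band) with a JSON sidecar ``<stem>.bands.json`` holding the band wavelengths
and an intensity scale factor.  Reference concentrations (micrograms of
astaxanthin per gram of fish, measured in duplicate by HPLC) travel as plain
CSV tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VIDEOMETER_WAVELENGTHS_NM",
    "NOMINAL_REFLECTANCE_CEILING",
    "BandSet",
    "SpectralCube",
    "Mask",
    "ReferenceTable",
    "AbsorbanceSpectrum",
    "absorbance_to_reflectance",
    "reflectance_to_absorbance",
    "read_cube",
    "write_cube",
    "read_reference",
    "write_reference",
    "read_mask",
    "write_mask",
    "MetadataError",
    "ShapeError",
    "DomainError",
]

#: Peak wavelengths (nm) of the 19 narrow-band LEDs of the VideometerLab
#: instrument, in increasing order.
VIDEOMETER_WAVELENGTHS_NM: tuple[float, ...] = (
    395.0, 435.0, 450.0, 470.0, 505.0, 525.0, 570.0, 590.0, 630.0, 645.0,
    660.0, 700.0, 850.0, 870.0, 890.0, 910.0, 940.0, 950.0, 970.0,
)

#: Reflectance values are nominally in [0, 1]; mild specular excess up to
#: this ceiling is tolerated by the data model and the file format.
NOMINAL_REFLECTANCE_CEILING = 1.2

_UINT16_MAX = 65535


class MetadataError(ValueError):
    """Raised when a cube file lacks or disagrees with its sidecar metadata."""


class ShapeError(ValueError):
    """Raised when array dimensions are inconsistent with their contract."""


class DomainError(ValueError):
    """Raised when a numeric argument is outside its mathematical domain."""


# ---------------------------------------------------------------------------
# Band sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSet:
    """Ordered collection of band-center wavelengths.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing band centers in nanometres; all must lie in the
        instrument-plausible window [350, 1100] nm.
    names
        Optional human-readable labels, one per band.
    """

    wavelengths_nm: tuple[float, ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", wl)
        if len(wl) == 0:
            raise DomainError("BandSet needs at least one wavelength")
        arr = np.asarray(wl)
        if np.any(np.diff(arr) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if arr.min() < 350.0 or arr.max() > 1100.0:
            raise DomainError("wavelengths must lie in [350, 1100] nm")
        if self.names is not None and len(self.names) != len(wl):
            raise ShapeError("names length must match wavelengths length")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)

    @classmethod
    def videometer(cls) -> "BandSet":
        """The default 19-band VideometerLab band set (395-970 nm)."""
        return cls(VIDEOMETER_WAVELENGTHS_NM)

    def visible(self, upper_nm: float = 700.0) -> "BandSet":
        """Sub-band-set at or below ``upper_nm`` (visible range by default)."""
        wl = tuple(w for w in self.wavelengths_nm if w <= upper_nm)
        return BandSet(wl)

    def visible_indices(self, upper_nm: float = 700.0) -> np.ndarray:
        return np.flatnonzero(self.array <= upper_nm)


# ---------------------------------------------------------------------------
# Cubes and masks
# ---------------------------------------------------------------------------

@dataclass
class SpectralCube:
    """``H x W x B`` reflectance image with its band wavelengths.

    Reflectance is dimensionless, nominally in ``[0, 1.2]``; negative values
    are rejected.  ``pixel_size`` is an optional physical scale in mm/pixel.
    """

    data: np.ndarray
    bands: BandSet
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("cube data must be H x W x B")
        h, w, b = self.data.shape
        if h < 1 or w < 1:
            raise ShapeError("cube must have H, W >= 1")
        if b != len(self.bands):
            raise ShapeError(
                f"cube has {b} planes but band set has {len(self.bands)}"
            )
        if np.any(self.data < 0):
            raise DomainError("reflectance values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixels(self, mask: "Mask | np.ndarray | None" = None) -> np.ndarray:
        """Flatten to an ``(n_pixels, B)`` matrix, optionally within a mask."""
        if mask is None:
            return self.data.reshape(-1, self.n_bands)
        m = mask.data if isinstance(mask, Mask) else np.asarray(mask, bool)
        if m.shape != self.data.shape[:2]:
            raise ShapeError("mask shape does not match cube")
        return self.data[m]


MASK_LABELS = ("background", "fillet", "fat", "roi")


@dataclass
class Mask:
    """Boolean ``H x W`` mask with a semantic label."""

    data: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ShapeError("mask must be 2-D")
        if self.label not in MASK_LABELS:
            raise DomainError(f"label must be one of {MASK_LABELS}")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "Mask") -> np.ndarray:
        return self.data & other.data

    def __invert__(self) -> np.ndarray:
        return ~self.data


def roi_from(fillet: Mask, fat: Mask) -> Mask:
    """Region of interest: fillet pixels that are not fat/collagen."""
    if fillet.data.shape != fat.data.shape:
        raise ShapeError("fillet and fat masks differ in shape")
    return Mask(fillet.data & ~fat.data, "roi")


# ---------------------------------------------------------------------------
# Reference chemistry
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Per-sample astaxanthin reference concentrations (µg/g fish).

    Chemical reference values are determined in duplicate; the working
    concentration is the mean of the two replicates, which are retained for
    audit.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "replicate_a", "replicate_b")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise MetadataError(f"reference table missing column {col!r}")
        for col in ("replicate_a", "replicate_b"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df["sample_id"].duplicated().any():
            raise DomainError("sample_ids must be unique")
        if (df[["replicate_a", "replicate_b"]] < 0).any().any():
            raise DomainError("concentrations must be non-negative")
        df["concentration"] = df[["replicate_a", "replicate_b"]].mean(axis=1)
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def concentrations(self) -> np.ndarray:
        return self.frame["concentration"].to_numpy(dtype=float)

    @classmethod
    def from_rows(
        cls, rows: Sequence[tuple[str, float, float]]
    ) -> "ReferenceTable":
        df = pd.DataFrame(rows, columns=["sample_id", "replicate_a", "replicate_b"])
        return cls(df)


# ---------------------------------------------------------------------------
# Absorbance <-> reflectance
# ---------------------------------------------------------------------------

@dataclass
class AbsorbanceSpectrum:
    """Absorbance spectrum A(lambda) from a scanning spectrometer (A >= 0)."""

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths_nm.shape != self.absorbance.shape:
            raise ShapeError("wavelength and absorbance vectors differ in length")
        if np.any(self.absorbance < 0):
            raise DomainError("absorbance must be non-negative")


def absorbance_to_reflectance(a: AbsorbanceSpectrum | np.ndarray) -> np.ndarray:
    """Convert absorbance to reflectance via R = 10**(-A).

    The spectrophotometric convention A = log10(1/R); A = 0 is a perfect
    reflector (R = 1) and each unit of absorbance attenuates tenfold.
    """
    arr = a.absorbance if isinstance(a, AbsorbanceSpectrum) else np.asarray(a, float)
    if np.any(arr < 0):
        raise DomainError("absorbance must be non-negative")
    return np.power(10.0, -arr)


def reflectance_to_absorbance(r: np.ndarray) -> np.ndarray:
    """Inverse of :func:`absorbance_to_reflectance`: A = -log10(R), R in (0, 1]."""
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise DomainError("reflectance must lie in (0, 1] for absorbance conversion")
    return -np.log10(arr)


# ---------------------------------------------------------------------------
# Cube file I/O: multi-page 16-bit TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".bands.json") if path.suffix == "" \
        else path.parent / (path.stem + ".bands.json")


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as a multi-page 16-bit TIFF plus a JSON sidecar.

    Values are quantized to 16 bits relative to ``scale = max(1, data.max())``
    so that ordinary reflectances round-trip within 1/65535 while specular
    excess above 1.0 is preserved through the stored scale factor.
    """
    path = Path(path)
    h, w, b = cube.shape
    if h == 0 or w == 0:
        raise ShapeError("cannot write an empty cube")
    scale = float(max(1.0, cube.data.max())) if cube.data.size else 1.0
    quant = np.round(cube.data / scale * _UINT16_MAX).astype(np.uint16)
    pages = np.moveaxis(quant, 2, 0)  # one TIFF page per band
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "wavelengths_nm": list(cube.bands.wavelengths_nm),
        "scale": scale,
    }
    if cube.pixel_size is not None:
        sidecar["pixel_size_mm"] = cube.pixel_size
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_cube(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_cube`."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise MetadataError(f"missing band sidecar {side.name}")
    meta = json.loads(side.read_text())
    if "wavelengths_nm" not in meta:
        raise MetadataError("sidecar lacks 'wavelengths_nm'")
    wavelengths = meta["wavelengths_nm"]
    scale = float(meta.get("scale", 1.0))
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.shape[0] != len(wavelengths):
        raise ShapeError(
            f"TIFF has {pages.shape[0]} pages but sidecar lists "
            f"{len(wavelengths)} wavelengths"
        )
    data = np.moveaxis(pages.astype(float), 0, 2) / _UINT16_MAX * scale
    return SpectralCube(
        data, BandSet(tuple(wavelengths)), pixel_size=meta.get("pixel_size_mm")
    )


# ---------------------------------------------------------------------------
# Reference table I/O
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> ReferenceTable:
    """Read a reference CSV with header ``sample_id,replicate_a,replicate_b``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    try:
        return ReferenceTable(df)
    except (ValueError, TypeError) as exc:
        raise MetadataError(f"cannot parse reference table {path}: {exc}") from exc


def write_reference(table: ReferenceTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame[["sample_id", "replicate_a", "replicate_b"]].to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# Mask I/O (PNG, 0/255)
# ---------------------------------------------------------------------------

def write_mask(mask: Mask, path: str | Path) -> Path:
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (mask.data.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, label: str) -> Mask:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return Mask(img > 127, label)
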