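"""Otsu thresholding, fillet/fat segmentation, and mean-spectrum extraction.

The region of interest (ROI) of a fillet image is built in two stages:

1. the fillet is separated from the background (petri dish / cardboard)
   by Otsu-thresholding the first MNF component, whose spatial smoothness
   contrasts object against background;
2. fat/collagen structures are removed by Otsu-thresholding the canonical
   variate of a two-class CDA trained on seed regions of meat and fat.

Each cube then contributes a single spectrum: the arithmetic mean over its
ROI pixels, band by band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cube_model import DomainError, Mask, ShapeError, SpectralCube, roi_from
from .decomposition import cda, mnf

__all__ = [
    "otsu_threshold",
    "segment_fillet",
    "segment_fat",
    "extract_mean_spectrum",
    "SegmentationError",
]

logger = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when a segmentation stage produces an unusable mask."""


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance (Otsu).

    The value range is binned into ``bins`` equal-width cells; the returned
    threshold is the upper edge of the best cut, i.e. pixels with
    ``value <= threshold`` form the lower class.  Ties in the between-class
    variance are broken toward the lower threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise DomainError("otsu needs at least two distinct finite values")

    counts, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    total = counts.sum()
    # The objective is invariant under affine maps of the class values, so
    # the bin index serves as the value: all sums are then exact in float64
    # and tie-breaking is deterministic.
    idx = np.arange(bins, dtype=float)
    w0 = np.cumsum(counts).astype(float)        # pixels at or below cut i
    m0 = np.cumsum(counts * idx)
    w1 = total - w0
    # between-class variance for each cut after bin i (i = 0..bins-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (m0[-1] - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b = np.where((w0 == 0) | (w1 == 0), -np.inf, sigma_b)[:-1]
    if not np.isfinite(sigma_b).any():
        raise DomainError("degenerate histogram: all mass in one bin")
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) tie
    return float(edges[best + 1])


# ---------------------------------------------------------------------------
# Fillet segmentation
# ---------------------------------------------------------------------------

def _border_majority(mask: np.ndarray) -> float:
    """Fraction of image-border pixels that are True in ``mask``."""
    border = np.concatenate(
        [mask[0, :], mask[-1, :], mask[1:-1, 0], mask[1:-1, -1]]
    )
    return float(border.mean())


def segment_fillet(cube: SpectralCube) -> dict[str, Mask]:
    """Separate fillet from background via MNF component 1 + Otsu.

    The Otsu side holding the majority of image-border pixels is labelled
    background.  The foreground is cleaned by keeping its largest connected
    component and filling holes.
    """
    dec = mnf(cube)
    if dec.eigenvalues[0] > 0.5:
        # even the smoothest component is mostly noise: no object present
        raise SegmentationError(
            "no coherent spatial structure found (image appears to be "
            "background only)"
        )
    score = dec.scores[..., 0]
    thr = otsu_threshold(score)
    low = score <= thr
    # the class covering most of the border is the background
    background_is_low = _border_majority(low) >= _border_majority(~low)
    fg = ~low if background_is_low else low
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")

    labeled, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
    fg = labeled == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        raise SegmentationError("empty fillet mask")
    logger.debug("fillet mask: %d pixels", int(fg.sum()))
    return {
        "background": Mask(~fg, "background"),
        "fillet": Mask(fg, "fillet"),
    }


# ---------------------------------------------------------------------------
# Fat removal
# ---------------------------------------------------------------------------

def segment_fat(
    cube: SpectralCube,
    fillet: Mask,
    seed_labels: dict[str, Mask | np.ndarray],
) -> Mask:
    """Remove fat/collagen inside the fillet via CDA + Otsu.

    ``seed_labels`` supplies training regions ``{"meat": ..., "fat": ...}``;
    the canonical variate of the two-class CDA is thresholded within the
    fillet, and the side whose mean matches the fat seed class is labelled
    fat.  Fat pixels must additionally lie on the fat side of the midpoint
    between the seed-class means; if the seed classes are not separable on
    the variate (Cohen's d below 2) no fat is declared.
    """
    if not fillet.data.any():
        raise DomainError("fillet mask is empty")
    seeds = {}
    for name in ("meat", "fat"):
        if name not in seed_labels:
            raise DomainError(f"seed_labels must include {name!r}")
        m = seed_labels[name]
        seeds[name] = m.data if isinstance(m, Mask) else np.asarray(m, bool)
        if seeds[name].shape != cube.data.shape[:2]:
            raise ShapeError(f"{name} seed mask shape mismatch")
        if seeds[name].sum() < 2:
            raise DomainError(f"seed class {name!r} needs >= 2 pixels")

    x = np.concatenate([cube.data[seeds["meat"]], cube.data[seeds["fat"]]])
    y = np.concatenate(
        [np.zeros(seeds["meat"].sum(), int), np.ones(seeds["fat"].sum(), int)]
    )
    dec = cda(x, y)
    w = dec.vectors[:, 0]
    variate = (cube.data - dec.center) @ w

    inside = variate[fillet.data]
    fat_proj = cube.data[seeds["fat"]] @ w
    meat_proj = cube.data[seeds["meat"]] @ w
    pooled_sd = np.sqrt(0.5 * (fat_proj.var(ddof=1) + meat_proj.var(ddof=1)))
    separation = abs(fat_proj.mean() - meat_proj.mean())
    if pooled_sd > 0 and separation / pooled_sd < 2.0:
        logger.warning(
            "seed classes not separable on the canonical variate "
            "(d=%.2f); declaring no fat", separation / pooled_sd,
        )
        return Mask(np.zeros_like(fillet.data), "fat")

    thr = otsu_threshold(inside)
    fat_is_high = fat_proj.mean() > meat_proj.mean()
    fat = (variate > thr) if fat_is_high else (variate <= thr)
    # guard against unimodal splits: fat must also lie on the fat side of
    # the midpoint between the seed-class means
    mid = 0.5 * (fat_proj.mean() + meat_proj.mean()) - dec.center @ w
    fat &= (variate > mid) if fat_is_high else (variate < mid)
    fat = fat & fillet.data
    logger.debug("fat mask: %d of %d fillet pixels", fat.sum(), fillet.n_pixels)
    return Mask(fat, "fat")


def segment_sample(
    cube: SpectralCube,
    seed_labels: dict[str, Mask | np.ndarray] | None = None,
) -> dict[str, Mask]:
    """Full segmentation: background/fillet plus optional fat removal.

    Returns masks ``background``, ``fillet``, ``fat`` and ``roi``; when no
    seed labels are available the fat mask is empty and the ROI equals the
    fillet.
    """
    masks = segment_fillet(cube)
    if seed_labels is not None:
        fat = segment_fat(cube, masks["fillet"], seed_labels)
    else:
        fat = Mask(np.zeros(cube.data.shape[:2], bool), "fat")
    masks["fat"] = fat
    masks["roi"] = roi_from(masks["fillet"], fat)
    if masks["roi"].n_pixels == 0:
        raise SegmentationError("empty ROI after fat removal")
    return masks


# ---------------------------------------------------------------------------
# Spectrum extraction
# ---------------------------------------------------------------------------

def extract_mean_spectrum(cube: SpectralCube, roi: Mask | np.ndarray) -> np.ndarray:
    """Mean reflectance over ROI pixels, one value per band."""
    m = roi.data if isinstance(roi, Mask) else np.asarray(roi, bool)
    if m.shape != cube.data.shape[:2]:
        raise ShapeError("roi shape does not match cube")
    if not m.any():
        raise DomainError("roi is empty")
    return cube.data[m].mean(axis=0)
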