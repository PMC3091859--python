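"""Statistical orthogonal decompositions for cubes and spectra matrices.

Three linear transforms drive segmentation and exploratory analysis:

* **PCA** — eigenvectors of the sample covariance, for trend visualization
  and outlier screening of mean spectra;
* **MNF** (maximum noise fraction) — generalized eigenproblem of a
  shift-difference noise covariance against the total covariance, ordering
  components by signal-to-noise; used to separate fillet from background.
  With noise estimated from single-offset pixel differences this coincides
  with the maximum autocorrelation factor (MAF) transform, so one
  implementation serves both names;
* **CDA** (canonical discriminant analysis) — Fisher's between- over
  within-class scatter problem, used to isolate fat/collagen from flesh.

All solvers share a sign convention (each component's largest-magnitude
entry is positive) and regularize only when a scatter matrix is numerically
singular, with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .cube_model import DomainError, Mask, ShapeError, SpectralCube

__all__ = ["LinearDecomposition", "pca", "mnf", "cda"]

logger = logging.getLogger(__name__)

#: Relative ridge added to a scatter matrix only when it is numerically
#: singular (Cholesky failure): eps = RIDGE_REL * trace / p.
RIDGE_REL = 1e-8


@dataclass
class LinearDecomposition:
    """Result of a linear transform of spectra.

    ``vectors`` is ``p x k`` (one column per component); ``scores`` is the
    projection of the input onto those columns, shaped like the input
    (``n x k`` for matrices, ``H x W x k`` for cubes).  ``eigenvalues``
    carries the solver's natural spectrum: explained variances for PCA,
    noise fractions for MNF, separability ratios for CDA.
    """

    kind: str
    vectors: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    center: np.ndarray
    explained_variance_ratio: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.vectors.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (sign convention)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def _regularize_if_singular(m: np.ndarray, name: str) -> np.ndarray:
    """Add a tiny ridge only when ``m`` is not positive definite."""
    try:
        linalg.cholesky(m, lower=True)
        return m
    except linalg.LinAlgError:
        eps = RIDGE_REL * np.trace(m) / m.shape[0]
        if eps <= 0:
            eps = RIDGE_REL
        warnings.warn(
            f"{name} is numerically singular; adding ridge {eps:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
        logger.warning("%s singular, ridge %.3e applied", name, eps)
        return m + eps * np.eye(m.shape[0])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(x: np.ndarray, k: int | None = None) -> LinearDecomposition:
    """Principal component analysis of an ``n x p`` matrix.

    The matrix is centered internally (autoscale upstream if desired);
    components are the top-``k`` eigenvectors of the sample covariance
    (``n-1`` denominator), ordered by decreasing explained variance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ShapeError("pca expects an n x p matrix")
    n, p = x.shape
    if n < 2:
        raise DomainError("pca needs n >= 2 samples")
    kmax = min(n - 1, p)
    if k is None:
        k = kmax
    if not 1 <= k <= kmax:
        raise DomainError(f"k must lie in [1, {kmax}]")

    center = x.mean(axis=0)
    xc = x - center
    # SVD route: numerically stabler than forming the covariance
    u, s, vt = linalg.svd(xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    vectors = _fix_signs(vt[:k].T)
    scores = xc @ vectors
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return LinearDecomposition(
        kind="pca",
        vectors=vectors,
        scores=scores,
        eigenvalues=var[:k],
        center=center,
        explained_variance_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# MNF
# ---------------------------------------------------------------------------

def _noise_covariance(
    data: np.ndarray, mask: np.ndarray | None, offset: tuple[int, int]
) -> np.ndarray:
    """Noise covariance from half-differences of offset-adjacent pixels."""
    dr, dc = offset
    h, w, _ = data.shape
    a = data[: h - dr if dr else h, : w - dc if dc else w]
    b = data[dr:, dc:]
    diff = (a - b).reshape(-1, data.shape[2])
    if mask is not None:
        ma = mask[: h - dr if dr else h, : w - dc if dc else w]
        mb = mask[dr:, dc:]
        keep = (ma & mb).ravel()
        diff = diff[keep]
    if diff.shape[0] < 2:
        raise DomainError("not enough pixel pairs to estimate noise covariance")
    return np.cov(diff, rowvar=False, ddof=1) / 2.0


def mnf(
    cube: SpectralCube,
    mask: Mask | None = None,
    offset: tuple[int, int] = (0, 1),
) -> LinearDecomposition:
    """Maximum noise fraction transform of a cube.

    Solves the generalized eigenproblem ``Sigma_N v = lambda Sigma v`` where
    ``Sigma_N`` is estimated from half-differences of pixels at the given
    shift ``offset`` (default: horizontal neighbours) and ``Sigma`` is the
    total covariance.  Components are ordered by increasing noise fraction
    ``lambda`` (decreasing SNR), so component 1 is the smoothest spatial
    structure in the image.
    """
    data = cube.data
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ShapeError("mnf needs at least a 2 x 2 image")
    m = mask.data if mask is not None else None

    pixels = data[m] if m is not None else data.reshape(-1, cube.n_bands)
    if pixels.shape[0] < 2:
        raise DomainError("not enough pixels for covariance")
    center = pixels.mean(axis=0)
    sigma = np.cov(pixels, rowvar=False, ddof=1)
    sigma_n = _noise_covariance(data, m, offset)

    sigma = _regularize_if_singular(np.atleast_2d(sigma), "total covariance")
    evals, evecs = linalg.eigh(np.atleast_2d(sigma_n), sigma)
    order = np.argsort(evals)  # increasing noise fraction = decreasing SNR
    evals, evecs = evals[order], evecs[:, order]
    vectors = _fix_signs(evecs)
    scores = (data - center) @ vectors
    return LinearDecomposition(
        kind="mnf",
        vectors=vectors,
        scores=scores,
        eigenvalues=evals,
        center=center,
    )


# ---------------------------------------------------------------------------
# CDA
# ---------------------------------------------------------------------------

def cda(x: np.ndarray, labels: np.ndarray) -> LinearDecomposition:
    """Canonical discriminant analysis (Fisher) of labelled spectra.

    Maximizes between-class over within-class scatter via the generalized
    eigenproblem ``S_B v = lambda S_W v``; returns ``min(n_classes - 1, p)``
    canonical variates ordered by decreasing separability.  For two classes
    the single variate is proportional to Fisher's direction
    ``S_W^{-1} (mu_1 - mu_2)``.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2:
        raise ShapeError("cda expects an n x p matrix")
    if labels.shape[0] != x.shape[0]:
        raise ShapeError("labels length must match rows of x")
    classes, inverse = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise DomainError("cda needs at least two classes")
    counts = np.bincount(inverse)
    if np.any(counts < 2):
        raise DomainError("each class needs at least two samples")

    n, p = x.shape
    grand = x.mean(axis=0)
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    for k, cls in enumerate(classes):
        xk = x[inverse == k]
        mk = xk.mean(axis=0)
        dk = xk - mk
        s_w += dk.T @ dk
        dm = (mk - grand)[:, None]
        s_b += counts[k] * (dm @ dm.T)

    s_w = _regularize_if_singular(s_w, "within-class scatter")
    k_out = min(classes.size - 1, p)
    evals, evecs = linalg.eigh(s_b, s_w)
    order = np.argsort(evals)[::-1][:k_out]
    vectors = _fix_signs(evecs[:, order])
    scores = (x - grand) @ vectors
    return LinearDecomposition(
        kind="cda",
        vectors=vectors,
        scores=scores,
        eigenvalues=evals[order],
        center=grand,
    )
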