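"""Autoscaling, PLSR calibration with LOOCV, metrics and outlier screening.

Mean ROI spectra are collinear — neighbouring bands carry nearly the same
information — so calibration against chemical reference concentrations uses
partial least squares regression (PLSR).  The workflow is:

1. autoscale the spectra matrix (subtract each band's mean, divide by its
   standard deviation) and standardize the response;
2. choose the number of latent components A by leave-one-out
   cross-validation (LOOCV) on the training set, minimizing RMSECV;
3. fit the final model and validate on an independent test set via RMSEP,
   the coefficient of determination R², and the standard error of the
   residuals;
4. screen calibration samples for outliers with Hotelling's T² on the first
   principal component scores.

PLSR is implemented as univariate-y NIPALS with X-deflation; the regression
vector ``b = W (PᵀW)⁻¹ q`` reproduces training predictions on its own, which
is what pixel-wise concentration mapping relies on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cube_model import DomainError, ShapeError
from .decomposition import pca

__all__ = [
    "AutoscaleParams",
    "PLSModel",
    "CVResult",
    "PredictionMetrics",
    "autoscale_fit",
    "autoscale_apply",
    "plsr_fit",
    "predict",
    "loocv_select",
    "metrics",
    "screen_outliers",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AutoscaleParams:
    """Column means and standard deviations (n-1 denominator) of training X."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ShapeError("mean and sd must have equal shapes")
        if np.any(self.sd <= 0):
            raise DomainError("sd must be positive elementwise")


def autoscale_fit(x: np.ndarray) -> AutoscaleParams:
    """Fit per-column standardization parameters on a training matrix."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DomainError("autoscale_fit needs an n x p matrix with n >= 2")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DomainError(f"constant column(s) at index {bad.tolist()}")
    return AutoscaleParams(mean, sd)


def autoscale_apply(x: np.ndarray, params: AutoscaleParams) -> np.ndarray:
    """Standardize with *training* parameters (never recomputed)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.mean.shape[0]:
        raise ShapeError("column count does not match autoscale parameters")
    return (x - params.mean) / params.sd


# ---------------------------------------------------------------------------
# PLSR (univariate-y NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS regression model on autoscaled X and standardized y."""

    autoscale: AutoscaleParams
    y_mean: float
    y_sd: float
    weights: np.ndarray      # W, p x A
    x_loadings: np.ndarray   # P, p x A
    y_loadings: np.ndarray   # q, length A
    coef: np.ndarray         # b, length p, on the autoscaled/standardized scale
    n_components: int

    @property
    def n_features(self) -> int:
        return self.coef.shape[0]


def _nipals_path(xs: np.ndarray, ys: np.ndarray, a_max: int):
    """NIPALS with X-deflation; returns (W, P, q) for components 1..a_max."""
    n, p = xs.shape
    w_list, p_list, q_list = [], [], []
    x, y = xs.copy(), ys.copy()
    for _ in range(a_max):
        cov = x.T @ y
        norm = np.linalg.norm(cov)
        if norm == 0:
            break  # nothing left to model
        w = cov / norm
        t = x @ w
        tt = t @ t
        if tt == 0:
            break
        p_vec = x.T @ t / tt
        q = (y @ t) / tt
        x = x - np.outer(t, p_vec)
        y = y - q * t
        w_list.append(w)
        p_list.append(p_vec)
        q_list.append(q)
    w_mat = np.column_stack(w_list) if w_list else np.zeros((p, 0))
    p_mat = np.column_stack(p_list) if p_list else np.zeros((p, 0))
    return w_mat, p_mat, np.asarray(q_list)


def _coef_from_loadings(w: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vector b = W (PᵀW)⁻¹ q on the standardized scale."""
    if w.shape[1] == 0:
        return np.zeros(w.shape[0])
    return w @ np.linalg.solve(p.T @ w, q)


def plsr_fit(x: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLSR model with ``n_components`` latent variables.

    X is autoscaled and y standardized internally; predictions are returned
    on the original concentration scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ShapeError("x must be n x p with one y per row")
    n, p = x.shape
    a_cap = min(p, n - 1)
    if not 1 <= n_components <= a_cap:
        raise DomainError(f"n_components must lie in [1, {a_cap}]")
    y_sd = float(np.std(y, ddof=1))
    if y_sd == 0:
        raise DomainError("response has zero variance")
    y_mean = float(y.mean())

    params = autoscale_fit(x)
    xs = autoscale_apply(x, params)
    ys = (y - y_mean) / y_sd
    w, p_mat, q = _nipals_path(xs, ys, n_components)
    coef = _coef_from_loadings(w, p_mat, q)
    return PLSModel(
        autoscale=params,
        y_mean=y_mean,
        y_sd=y_sd,
        weights=w,
        x_loadings=p_mat,
        y_loadings=q,
        coef=coef,
        n_components=w.shape[1],
    )


def predict(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    """Predict concentrations for new spectra (rows, or one vector)."""
    x_new = np.asarray(x_new, dtype=float)
    single = x_new.ndim == 1
    x2 = x_new[None, :] if single else x_new
    if x2.shape[1] != model.n_features:
        raise ShapeError(
            f"expected {model.n_features} bands, got {x2.shape[1]}"
        )
    xs = autoscale_apply(x2, model.autoscale)
    yhat = model.y_mean + (xs @ model.coef) * model.y_sd
    return float(yhat[0]) if single else yhat


# ---------------------------------------------------------------------------
# LOOCV component selection
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """RMSECV per candidate component count and the chosen count."""

    rmsecv: np.ndarray           # index a-1 -> RMSECV with a components
    chosen: int

    def __post_init__(self) -> None:
        expect = 1 + int(np.argmin(self.rmsecv))
        if self.chosen != expect:
            raise DomainError("chosen component count must be the argmin")


def loocv_select(x: np.ndarray, y: np.ndarray, a_max: int = 10) -> CVResult:
    """Pick the PLS component count minimizing leave-one-out RMSECV.

    For each left-out sample the autoscaling and the PLS fit are recomputed
    on the remaining samples (no information leakage); ties in the RMSECV
    curve resolve to the smallest component count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n < 3:
        raise DomainError("loocv needs at least 3 samples")
    cap = min(p, n - 2)
    if a_max > cap:
        warnings.warn(
            f"a_max={a_max} exceeds the LOOCV limit {cap}; capping",
            RuntimeWarning,
            stacklevel=2,
        )
        a_max = cap
    if a_max < 1:
        raise DomainError("no usable component count")

    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        params = autoscale_fit(xi)
        ys = (yi - yi.mean()) / np.std(yi, ddof=1)
        w, p_mat, q = _nipals_path(autoscale_apply(xi, params), ys, a_max)
        xs_test = autoscale_apply(x[i], params)
        for a in range(1, a_max + 1):
            a_eff = min(a, w.shape[1])
            coef = _coef_from_loadings(w[:, :a_eff], p_mat[:, :a_eff], q[:a_eff])
            yhat = yi.mean() + (xs_test @ coef) * np.std(yi, ddof=1)
            press[a - 1] += (y[i] - yhat) ** 2
    rmsecv = np.sqrt(press / n)
    chosen = 1 + int(np.argmin(rmsecv))  # argmin takes the first minimum
    logger.debug("RMSECV curve %s, chosen A=%d", np.round(rmsecv, 4), chosen)
    return CVResult(rmsecv=rmsecv, chosen=chosen)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class PredictionMetrics:
    """Test-set quality numbers: R², RMSEP and the residuals' standard error."""

    r2: float
    rmsep: float
    std_error: float
    residuals: np.ndarray = field(repr=False)


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> PredictionMetrics:
    """RMSEP, R² and standard error of prediction residuals.

    ``rmsep = sqrt(mean((y - yhat)^2))``; ``r2 = 1 - SS_res / SS_tot``;
    ``std_error = sd(residuals, ddof=1) / sqrt(n)``.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ShapeError("need equal-length vectors with n >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("zero variance in y_true; r2 undefined")
    resid = y_true - y_pred
    rmsep = float(np.sqrt(np.mean(resid**2)))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    std_error = float(np.std(resid, ddof=1) / np.sqrt(resid.size))
    return PredictionMetrics(r2=r2, rmsep=rmsep, std_error=std_error, residuals=resid)


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Hotelling-T² screening result with score-plot coordinates for review."""

    flagged: np.ndarray          # indices into the input rows
    t_squared: np.ndarray
    threshold: float
    scores: np.ndarray           # n x n_pc PCA scores


def screen_outliers(
    x: np.ndarray, n_pc: int = 2, alpha: float = 0.975
) -> OutlierReport:
    """Flag outlying spectra by Hotelling's T² on autoscaled PCA scores.

    T² is computed on the first ``n_pc`` principal components of the
    autoscaled matrix; samples above the ``alpha`` quantile of the exact
    T² null distribution (an F distribution, scaled) are flagged.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise DomainError("outlier screening needs n >= 5")
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    xs = autoscale_apply(x, autoscale_fit(x))
    dec = pca(xs, k=min(n_pc, min(n - 1, x.shape[1])))
    scores = dec.scores
    lam = dec.eigenvalues
    t2 = np.sum(scores**2 / lam, axis=1)
    k = scores.shape[1]
    fcrit = stats.f.ppf(alpha, k, n - k)
    threshold = k * (n - 1) / (n - k) * fcrit
    flagged = np.flatnonzero(t2 > threshold)
    logger.debug("T2 screening flagged %d / %d samples", flagged.size, n)
    return OutlierReport(
        flagged=flagged, t_squared=t2, threshold=float(threshold), scores=scores
    )
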