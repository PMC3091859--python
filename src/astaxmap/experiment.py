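"""End-to-end experiment driver: simulate, segment, calibrate, evaluate, map.

One configuration object drives the whole workflow the package implements:

1. generate a synthetic cohort (59 fillet phantoms by default) with known
   reference concentrations;
2. segment each cube (MNF + Otsu for the fillet, CDA + Otsu for fat) and
   extract the ROI mean spectrum; render the sRGB image and extract mean
   R, G, B;
3. split into training and test sets (20 / 39 by default), screen the
   training spectra for outliers (Hotelling T²), and calibrate a PLSR
   model with LOOCV-selected component count;
4. fit the matching 3-variable sRGB baseline model;
5. evaluate both models on the test set (R², RMSEP, standard error) and
   compute a pixel-wise concentration map for one test sample.

The emitted report is a plain JSON-serializable dictionary with a schema
version, reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .chemometrics import (
    PLSModel,
    loocv_select,
    metrics,
    plsr_fit,
    predict,
    screen_outliers,
)
from .colorimetry import cube_to_rgb, rgb_mean_features
from .cube_model import BandSet
from .mapping import ConcentrationMap, predict_map
from .segmentation import extract_mean_spectrum, segment_fat, segment_fillet
from .synthetic_fillet import CohortSpec, PhantomSample, PhantomSpec, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ConfigError",
    "run_experiment",
    "validate_report",
    "write_report",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

_REPORT_REQUIRED_KEYS = (
    "schema_version",
    "seed",
    "cohort",
    "outliers",
    "multispectral",
    "srgb",
    "predictions",
)


class ConfigError(ValueError):
    """Raised when an experiment configuration is invalid."""


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of the synthetic end-to-end experiment.

    Defaults reproduce the emulated study design: 59 samples, 20 training /
    39 test, up to 10 PLS components, additive reflectance noise SD 0.01.
    """

    seed: int = 1
    n_samples: int = 59
    n_train: int = 20
    n_test: int = 39
    target_mean: float = 1.69
    target_sd: float = 0.95
    lower: float = 0.20
    upper: float = 4.34
    noise_sd: float = 0.01
    brightness_sd: float = 0.05
    a_max: int = 10
    remove_outliers: bool = True
    outlier_alpha: float = 0.975
    outlier_n_pc: int = 2
    fat_removal: bool = True
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        problems = []
        if self.n_samples != self.n_train + self.n_test:
            problems.append("n_samples must equal n_train + n_test")
        if self.a_max < 1:
            problems.append("a_max must be >= 1")
        if not 0 < self.outlier_alpha < 1:
            problems.append("outlier_alpha must lie in (0, 1)")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_samples=self.n_samples,
            target_mean=self.target_mean,
            target_sd=self.target_sd,
            lower=self.lower,
            upper=self.upper,
            n_train=self.n_train,
            n_test=self.n_test,
            noise_sd=self.noise_sd,
            brightness_sd=self.brightness_sd,
            phantom=self.phantom,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        phantom_raw = raw.pop("phantom", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config fields: {unknown}")
        kwargs: dict[str, Any] = dict(raw)
        if phantom_raw is not None:
            pknown = {f.name for f in dataclasses.fields(PhantomSpec)}
            punknown = sorted(set(phantom_raw) - pknown)
            if punknown:
                raise ConfigError(f"unknown phantom fields: {punknown}")
            kwargs["phantom"] = PhantomSpec(**phantom_raw)
        return cls(**kwargs)


@dataclass
class ExperimentResult:
    """Report dictionary plus the heavyweight objects behind it."""

    report: dict[str, Any]
    samples: list[PhantomSample]
    spectra: np.ndarray
    rgb_features: np.ndarray
    model: PLSModel
    rgb_model: PLSModel
    example_map: ConcentrationMap | None


def _segment_and_extract(
    sample: PhantomSample, fat_removal: bool
) -> tuple[np.ndarray, np.ndarray, Any]:
    """Segment one phantom and return (mean spectrum, rgb features, roi)."""
    masks = segment_fillet(sample.cube)
    fillet = masks["fillet"]
    if fat_removal:
        # CDA seed regions come from the phantom's ground-truth masks
        seed_labels = {
            "meat": sample.fillet.data & ~sample.fat.data,
            "fat": sample.fat.data,
        }
        if seed_labels["fat"].sum() >= 2:
            fat = segment_fat(sample.cube, fillet, seed_labels)
            roi_data = fillet.data & ~fat.data
        else:
            roi_data = fillet.data
    else:
        roi_data = fillet.data
    from .cube_model import Mask

    roi = Mask(roi_data, "roi")
    spectrum = extract_mean_spectrum(sample.cube, roi)
    rgb = cube_to_rgb(sample.cube)
    features = rgb_mean_features(rgb, roi)
    return spectrum, features, roi


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full synthetic calibration experiment; deterministic per seed."""
    config = config or ExperimentConfig()
    t0 = time.perf_counter()
    bands = BandSet.videometer()
    cspec = config.cohort_spec()
    samples, reference = generate_cohort(cspec)
    y = reference.concentrations
    logger.info(
        "cohort generated: n=%d, mean=%.3f, sd=%.3f (%.1fs)",
        len(samples), y.mean(), y.std(ddof=1), time.perf_counter() - t0,
    )

    t1 = time.perf_counter()
    spectra, rgb_feats, rois = [], [], []
    for sample in samples:
        spectrum, features, roi = _segment_and_extract(sample, config.fat_removal)
        spectra.append(spectrum)
        rgb_feats.append(features)
        rois.append(roi)
    x = np.asarray(spectra)
    x_rgb = np.asarray(rgb_feats)
    logger.info("segmentation + extraction done (%.1fs)", time.perf_counter() - t1)

    # train/test split, randomized by the experiment seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    order = rng.permutation(config.n_samples)
    train_idx = np.sort(order[: config.n_train])
    test_idx = np.sort(order[config.n_train :])

    # outlier screening on the training pool only
    outlier_local: np.ndarray = np.array([], dtype=int)
    if config.remove_outliers:
        rep = screen_outliers(
            x[train_idx], n_pc=config.outlier_n_pc, alpha=config.outlier_alpha
        )
        outlier_local = rep.flagged
    outlier_idx = train_idx[outlier_local] if outlier_local.size else np.array([], int)
    kept_train = np.setdiff1d(train_idx, outlier_idx)

    # multispectral PLSR with LOOCV component choice
    cv = loocv_select(x[kept_train], y[kept_train], a_max=config.a_max)
    model = plsr_fit(x[kept_train], y[kept_train], cv.chosen)
    yhat_test = predict(model, x[test_idx])
    ms_metrics = metrics(y[test_idx], yhat_test)

    # sRGB baseline: 3 features
    cv_rgb = loocv_select(x_rgb[kept_train], y[kept_train], a_max=3)
    rgb_model = plsr_fit(x_rgb[kept_train], y[kept_train], cv_rgb.chosen)
    yhat_rgb = predict(rgb_model, x_rgb[test_idx])
    rgb_metrics = metrics(y[test_idx], yhat_rgb)

    # pixel-wise map for the first test sample
    map_sample = int(test_idx[0])
    example_map = predict_map(samples[map_sample].cube, rois[map_sample], model)

    ids = reference.sample_ids
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "cohort": {
            "n_samples": int(config.n_samples),
            "n_train": int(config.n_train),
            "n_test": int(config.n_test),
            "concentration_mean": float(y.mean()),
            "concentration_sd": float(np.std(y, ddof=1)),
            "concentration_min": float(y.min()),
            "concentration_max": float(y.max()),
        },
        "outliers": {
            "flagged_ids": [ids[i] for i in outlier_idx],
            "n_train_kept": int(kept_train.size),
        },
        "multispectral": {
            "chosen_components": int(cv.chosen),
            "rmsecv": [float(v) for v in cv.rmsecv],
            "r2": ms_metrics.r2,
            "rmsep": ms_metrics.rmsep,
            "std_error": ms_metrics.std_error,
        },
        "srgb": {
            "chosen_components": int(cv_rgb.chosen),
            "rmsecv": [float(v) for v in cv_rgb.rmsecv],
            "r2": rgb_metrics.r2,
            "rmsep": rgb_metrics.rmsep,
            "std_error": rgb_metrics.std_error,
        },
        "predictions": {
            "test_ids": [ids[i] for i in test_idx],
            "y_true": [float(v) for v in y[test_idx]],
            "y_pred_multispectral": [float(v) for v in yhat_test],
            "y_pred_srgb": [float(v) for v in yhat_rgb],
        },
        "map_sample_id": ids[map_sample],
        "map_roi_mean": example_map.roi_mean,
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }
    validate_report(report)
    logger.info(
        "experiment done: A=%d, RMSEP(ms)=%.4f, RMSEP(sRGB)=%.4f",
        cv.chosen, ms_metrics.rmsep, rgb_metrics.rmsep,
    )
    return ExperimentResult(
        report=report,
        samples=samples,
        spectra=x,
        rgb_features=x_rgb,
        model=model,
        rgb_model=rgb_model,
        example_map=example_map,
    )


def validate_report(report: dict[str, Any]) -> None:
    """Check the report against its schema; raise ConfigError on violation."""
    missing = [k for k in _REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ConfigError(f"report missing keys: {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ConfigError("unsupported report schema version")
    for section in ("multispectral", "srgb"):
        for key in ("r2", "rmsep", "std_error", "chosen_components"):
            if key not in report[section]:
                raise ConfigError(f"report[{section!r}] missing {key!r}")


def write_report(report: dict[str, Any], path: str | Path) -> Path:
    validate_report(report)
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path


def save_figures(result: ExperimentResult, outdir: str | Path) -> list[Path]:
    """Write the standard diagnostic figures (RMSECV curve, score plot,
    loadings plot, prediction map) as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .decomposition import pca
    from .chemometrics import autoscale_apply, autoscale_fit
    from .mapping import render_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = result.report
    wl = BandSet.videometer().array

    fig, ax = plt.subplots(figsize=(5, 3.5))
    curve = report["multispectral"]["rmsecv"]
    ax.plot(range(1, len(curve) + 1), curve, "o-")
    ax.axvline(report["multispectral"]["chosen_components"], ls="--", c="gray")
    ax.set_xlabel("PLS components")
    ax.set_ylabel("RMSECV (µg/g)")
    fig.tight_layout()
    p = outdir / "rmsecv.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    xs = autoscale_apply(result.spectra, autoscale_fit(result.spectra))
    dec = pca(xs, k=2)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(dec.scores[:, 0], dec.scores[:, 1], s=12)
    ax.set_xlabel(f"PC1 ({dec.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({dec.explained_variance_ratio[1]:.0%})")
    fig.tight_layout()
    p = outdir / "score_plot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    n_show = min(4, result.model.x_loadings.shape[1])
    for a in range(n_show):
        ax.plot(wl, result.model.x_loadings[:, a], marker="o", ms=3,
                label=f"loading {a + 1}")
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("PLS x-loading")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "loadings.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if result.example_map is not None:
        rgba = render_map(result.example_map)
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.imshow(rgba)
        ax.set_title(
            f"predicted map, ROI mean {result.example_map.roi_mean:.2f} µg/g"
        )
        ax.axis("off")
        fig.tight_layout()
        p = outdir / "prediction_map.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
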