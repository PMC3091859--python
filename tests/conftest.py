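"""Shared fixtures: small phantoms and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from astaxmap.cube_model import BandSet
from astaxmap.synthetic_fillet import (
    CohortSpec,
    EndmemberLibrary,
    PhantomSpec,
    render_phantom,
)


@pytest.fixture(scope="session")
def bands() -> BandSet:
    return BandSet.videometer()


@pytest.fixture(scope="session")
def endmembers(bands) -> EndmemberLibrary:
    return EndmemberLibrary.default(bands)


@pytest.fixture(scope="session")
def phantom():
    """Default-geometry phantom at the study's noise level (SD 0.01)."""
    return render_phantom(PhantomSpec(seed=1, noise_sd=0.01))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless phantom with a flat concentration field."""
    return render_phantom(
        PhantomSpec(seed=0, noise_sd=0.0, gradient_amplitude=0.0)
    )


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """Reduced cohort for fast pipeline tests (geometry scaled down)."""
    return CohortSpec(
        n_samples=16,
        n_train=8,
        n_test=8,
        noise_sd=0.005,
        seed=3,
        phantom=PhantomSpec(
            height=60, width=80, center=(30.0, 40.0), semi_axes=(20.0, 30.0)
        ),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
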