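"""Shared fixtures: seeded phantoms and fitted pipelines reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from dcesub.model import SubvolumeModel
from dcesub.phantom import (
    SMALL_GEOMETRY,
    AcquisitionConfig,
    generate_phantom,
)
from dcesub.preprocess import extract_aif

PHANTOM_SEED = 17


def _phantom(noise_sd_rel: float):
    acq = AcquisitionConfig(noise_sd_rel=noise_sd_rel, seed=PHANTOM_SEED)
    series, tumor, artery, truth = generate_phantom(acq, seed=PHANTOM_SEED)
    aif = extract_aif(series, artery)
    return {"series": series, "tumor": tumor, "artery": artery, "truth": truth, "aif": aif}


@pytest.fixture(scope="session")
def phantom_002():
    """Default phantom at the native dialect, 2% noise."""
    return _phantom(0.02)


@pytest.fixture(scope="session")
def phantom_005():
    """Default phantom at 5% noise."""
    return _phantom(0.05)


@pytest.fixture(scope="session")
def small_noise_free():
    """Reduced noise-free phantom (~800 tumor voxels) for PK round trips."""
    acq = AcquisitionConfig(noise_sd_rel=0.0, seed=5)
    series, tumor, artery, truth = generate_phantom(acq, geometry=SMALL_GEOMETRY, seed=5)
    aif = extract_aif(series, artery)
    return {"series": series, "tumor": tumor, "artery": artery, "truth": truth, "aif": aif}


def _fit(ph, kind: str):
    model = SubvolumeModel.from_series(
        ph["series"], ph["tumor"], ph["aif"], ph["truth"].label_map, feature_kind=kind
    )
    return model.fit(test_fraction=0.3, seed=0)


@pytest.fixture(scope="session")
def fitted_pca_002(phantom_002):
    return _fit(phantom_002, "pca")


@pytest.fixture(scope="session")
def fitted_wt_002(phantom_002):
    return _fit(phantom_002, "wt")


@pytest.fixture(scope="session")
def fitted_pca_005(phantom_005):
    return _fit(phantom_005, "pca")


@pytest.fixture(scope="session")
def fitted_wt_005(phantom_005):
    return _fit(phantom_005, "wt")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
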