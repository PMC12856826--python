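import numpy as np
import pytest

from lipidmsi import synthetic_data as sd
from lipidmsi.lipid_db import build_database
from lipidmsi.msi_core import (
    build_feature_matrix,
    extract_channels,
    mean_spectrum,
    select_threshold,
    tic_normalize,
)


@pytest.fixture(scope="session")
def default_db():
    return build_database()


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Phantom with all stochastic terms off: normalized spectra equal truth."""
    return sd.PhantomConfig(
        archetypes=(sd.lc_like(),),
        noise_cv=0.0,
        tic_cv=0.0,
        mz_jitter_ppm=0.0,
        baseline_fraction=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_cfg):
    return sd.make_phantom(noise_free_cfg)


def phantom_feature_matrix(cube, target_channels):
    """Normalize a cube and extract its channel feature matrix."""
    cube = tic_normalize(cube)
    mean = mean_spectrum(cube)
    thr, _ = select_threshold(mean, target_channels)
    channels = extract_channels(mean, thr)
    return cube, channels, build_feature_matrix(cube, channels)


@pytest.fixture(scope="session")
def blob_run():
    """Standard noisy packed-blob phantom taken to the feature-matrix stage."""
    cfg = sd.PhantomConfig(archetypes=(sd.lc_like(),), seed=42)
    cube, truth = sd.make_phantom(cfg)
    cube, channels, fm = phantom_feature_matrix(cube, 400)
    return cfg, truth, cube, channels, fm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
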