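"""Shared fixtures: default models and a small trained pipeline.

The session-scoped library/bundle fixtures keep the expensive pieces
(Gaussian fitting, network training) to a single run shared across test
modules.
"""

import numpy as np
import pytest

import multispot as ms


@pytest.fixture(scope="session")
def camera():
    return ms.CameraModel()


@pytest.fixture(scope="session")
def psf():
    return ms.PsfModel()


@pytest.fixture(scope="session")
def photon_dist():
    return ms.PhotonDistribution()


@pytest.fixture(scope="session")
def noise_free_camera():
    return ms.CameraModel(read_noise_e=0.0, background_photons_per_px=0.0)


@pytest.fixture(scope="session")
def small_library(psf, camera, photon_dist):
    """400-molecule noisy synthetic spot library with fits."""
    return ms.build_synthetic_library(400, psf, camera, photon_dist, rng=11)


@pytest.fixture(scope="session")
def noiseless_library(psf, noise_free_camera):
    """Noise-free library: fits recover the generator almost exactly."""
    return ms.build_synthetic_library(
        60, psf, noise_free_camera, ms.PhotonDistribution(family="constant", median=5000.0),
        rng=12, noise=False,
    )


@pytest.fixture(scope="session")
def mini_dataset(small_library):
    """Small balanced one/two-emitter dataset for training smoke tests."""
    return ms.build_dataset(small_library, 2500, (1, 2), rng=13)


@pytest.fixture(scope="session")
def mini_bundle(mini_dataset):
    """A quickly trained two-stage pipeline, good enough for routing tests."""
    cfg = ms.TrainConfig(epochs=35, seed=14)
    return ms.train_bundle(mini_dataset, cfg)
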