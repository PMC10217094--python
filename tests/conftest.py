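"""Shared fixtures: small synthetic cubes and scenes, generated at test time."""

import numpy as np
import pytest

from thermospec import HSICube, PlantMask, SceneConfig, TIRImage, make_scene


def linear_cube(k=204, shape=(8, 8), lo=400.0, hi=1000.0, values=None, seed=0):
    """A cube on the inclusive linear wavelength grid used by synthetic scenes."""
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 1.0, size=(k, *shape)).astype(np.float32)
    return HSICube(values, np.linspace(lo, hi, k))


@pytest.fixture(scope="session")
def default_scene():
    """One default-noise scene at reduced raster size (shared, read-only)."""
    return make_scene(SceneConfig(shape=(64, 64), seed=11))


@pytest.fixture(scope="session")
def noiseless_scene():
    """A noise- and quantisation-free scene: exact affine couplings."""
    cfg = SceneConfig(
        shape=(64, 64), channel_noise_sd=0.0, temp_noise_sd=0.0,
        quantization=0.0, seed=7,
    )
    return make_scene(cfg)


@pytest.fixture(scope="session")
def affine_channel_scene():
    """A hand-built scene where exactly one channel (143) is an exact affine
    image of the temperature raster and all other channels are independent
    noise around a plant/soil spectral contrast."""
    rng = np.random.default_rng(17)
    temps = np.round(rng.uniform(19.0, 24.0, (64, 64)), 1)
    tir = TIRImage(temps)
    k = 204
    values = rng.uniform(0.1, 0.6, size=(k, 64, 64)).astype(np.float32)
    # give the 450/550 pair a plant-like contrast so NDblue masking works
    blob = rng.random((64, 64)) > 0.5
    wl = np.linspace(400.0, 1000.0, k)
    i450 = int(np.argmin(np.abs(wl - 450)))
    i550 = int(np.argmin(np.abs(wl - 550)))
    values[i450] = np.where(blob, 0.05, 0.18) + rng.normal(0, 0.004, (64, 64))
    values[i550] = np.where(blob, 0.18, 0.19) + rng.normal(0, 0.004, (64, 64))
    values[143] = 0.05 + 0.02 * temps
    cube = HSICube(values, wl)
    return cube, tir, blob


@pytest.fixture()
def small_tir():
    rng = np.random.default_rng(3)
    return TIRImage(np.round(rng.uniform(18, 26, size=(32, 32)), 1))
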