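"""Synthetic aligned HSI/TIR scenes with the statistical structure the pipeline assumes.

Each scene is a linear-mixing world: blob-shaped plant regions on soil,
a per-pixel plant fraction ``mix`` in [0, 1] with a smooth boundary ramp
(emulating thermal pixels that straddle leaf and soil), per-pixel spectra

    R(c) = mix * plant(c) + (1 - mix) * soil(c) + channel noise,

and a temperature field

    T = mix * (T0 + stress) + (1 - mix) * (T0 + soil_offset) + temp noise,

so plants sit cooler than bare soil and a drought-stress offset warms
them over the key days.  One or more "coupled" channels are additionally
shifted by (T - T0) / beta, tying their reflectance affinely to
temperature; beta is negative by default because water-stressed (warmer)
tissue reflects less in the NIR.  With all noise off the coupled channel
is an exact affine image of temperature, so its correlation with the TIR
raster is exactly +/-1 by construction.  The TIR raster is optionally
quantised to the sensor step (0.1 deg C).

The plant and soil endmembers are fixed piecewise-linear reflectance
tables: a green-peak + red-edge + NIR-plateau curve for leaf tissue and a
nearly flat, mildly sloped curve for soil.  Only the 450/550 nm contrast
(which drives NDblue masking) and the NIR behaviour matter to the
pipeline; the curves make no radiative-transfer claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from . import io as tio
from .types import HSICube, PlantMask, TIRImage

#: The experiment's 7 key days (days since watering stopped).
KEY_DAYS: tuple[int, ...] = (1, 3, 6, 8, 12, 19, 25)

#: Default plant warming per key day, deg C: flat start, the early
#: ~0.2 deg step around day 6 (the earliest detectable stress event),
#: then a monotone rise to +2 deg as drought develops.
DEFAULT_STRESS_SCHEDULE: tuple[float, ...] = (0.0, 0.05, 0.2, 0.3, 0.6, 1.2, 2.0)

# (wavelength nm, reflectance) control points, linearly interpolated.
_PLANT_ENDMEMBER: tuple[tuple[float, float], ...] = (
    (400, 0.04), (450, 0.05), (500, 0.10), (550, 0.18), (600, 0.12),
    (650, 0.06), (680, 0.05), (700, 0.08), (720, 0.25), (740, 0.42),
    (780, 0.47), (820, 0.48), (900, 0.48), (1000, 0.47),
)
_SOIL_ENDMEMBER: tuple[tuple[float, float], ...] = ((400, 0.20), (1000, 0.26))


@dataclass
class SceneConfig:
    """Generator parameters; the defaults are the study conditions.

    beta couples temperature to the marked channels' reflectance
    (deg C per reflectance unit, negative: warmer tissue -> lower NIR
    reflectance); quantization is the TIR sensor step in deg C (0
    disables).  All randomness is determined by ``seed``.
    """

    shape: tuple[int, int] = (128, 128)
    n_channels: int = 204
    wl_lo: float = 400.0
    wl_hi: float = 1000.0
    coverage: float = 0.35                 # plant fraction of the raster
    boundary_sigma: float = 1.5            # px, leaf/soil mixing ramp width
    plant_threshold: float = 0.5           # mix above this = true plant pixel
    coupled_channels: tuple[int, ...] = (143,)
    beta: float = -15.0                    # deg C per reflectance unit
    t0: float = 20.0                       # deg C, unstressed plant temperature
    soil_offset: float = 3.0               # deg C, soil above t0
    stress_offset: float = 0.0             # deg C, plant warming (per-day)
    channel_noise_sd: float = 0.005        # reflectance units
    temp_noise_sd: float = 0.1             # deg C
    quantization: float = 0.1              # deg C TIR step; 0 = off
    plant_endmember: tuple[tuple[float, float], ...] = _PLANT_ENDMEMBER
    soil_endmember: tuple[tuple[float, float], ...] = _SOIL_ENDMEMBER
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must lie in (0, 1)")
        if self.channel_noise_sd < 0 or self.temp_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.quantization < 0:
            raise ValueError("quantization step must be >= 0")
        if self.beta == 0:
            raise ValueError("beta must be non-zero")
        for c in self.coupled_channels:
            if not 0 <= c < self.n_channels:
                raise ValueError(f"coupled channel {c} outside [0, {self.n_channels})")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_lo, self.wl_hi, self.n_channels)


@dataclass
class GroundTruth:
    """What the generator actually drew: mask, mixing fraction, clean temperature."""

    mask: np.ndarray           # (rows, cols) bool: mix > plant_threshold
    mix: np.ndarray            # (rows, cols) in [0, 1]
    temperature: np.ndarray    # (rows, cols) deg C, before quantisation
    config: SceneConfig

    @property
    def interior(self) -> np.ndarray:
        """Pixels that are pure plant (mix ~ 1), away from the mixed boundary."""
        return self.mix >= 1.0 - 1e-9

    def plant_mask(self, day: int = 0) -> PlantMask:
        return PlantMask(self.mask, thr=float("nan"), day=day)


@dataclass
class DayScene:
    day: int
    cube: HSICube
    tir: TIRImage
    truth: GroundTruth


def _plant_geometry(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Blob-shaped plant layout as a per-pixel mixing fraction."""
    rows, cols = config.shape
    field_ = rng.standard_normal((rows, cols))
    sigma = max(min(rows, cols) / 8.0, 2.0)
    smooth = ndimage.gaussian_filter(field_, sigma, mode="wrap")
    cut = np.quantile(smooth, 1.0 - config.coverage)
    binary = (smooth > cut).astype(np.float64)
    if config.boundary_sigma > 0:
        mix = ndimage.gaussian_filter(binary, config.boundary_sigma, mode="nearest")
        return np.clip(mix, 0.0, 1.0)
    return binary


def _render(
    config: SceneConfig,
    mix: np.ndarray,
    rng: np.random.Generator,
    day: int = 0,
) -> tuple[HSICube, TIRImage, GroundTruth]:
    wl = config.wavelengths
    plant = np.interp(wl, *zip(*config.plant_endmember))
    soil = np.interp(wl, *zip(*config.soil_endmember))

    temp = (
        mix * (config.t0 + config.stress_offset)
        + (1.0 - mix) * (config.t0 + config.soil_offset)
    )
    if config.temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, config.temp_noise_sd, size=mix.shape)

    cube_vals = (
        mix[None, :, :] * plant[:, None, None]
        + (1.0 - mix[None, :, :]) * soil[:, None, None]
    )
    shift = (temp - config.t0) / config.beta
    for c in config.coupled_channels:
        cube_vals[c] += shift
    if config.channel_noise_sd > 0:
        cube_vals = cube_vals + rng.normal(
            0.0, config.channel_noise_sd, size=cube_vals.shape
        )

    tir_vals = temp.copy()
    if config.quantization > 0:
        tir_vals = np.round(tir_vals / config.quantization) * config.quantization
    meta = {"synthetic": True, "day": day, "seed": config.seed}
    cube = HSICube(cube_vals.astype(np.float32), wl, dict(meta))
    tir = TIRImage(tir_vals, resolution=config.quantization or 0.1, meta=dict(meta))
    truth = GroundTruth(
        mask=mix > config.plant_threshold,
        mix=mix,
        temperature=temp,
        config=config,
    )
    return cube, tir, truth


def make_scene(config: SceneConfig) -> tuple[HSICube, TIRImage, GroundTruth]:
    """One aligned (cube, tir, truth) triple, fully determined by config.seed."""
    rng = np.random.default_rng(config.seed)
    mix = _plant_geometry(config, rng)
    return _render(config, mix, rng)


def make_timeseries(
    config: SceneConfig,
    stress_schedule: Sequence[float] | None = None,
    days: Sequence[int] = KEY_DAYS,
) -> list[DayScene]:
    """A key-day series of scenes sharing geometry and endmembers.

    ``stress_schedule`` gives the plant warming (deg C) per key day and
    must match ``days`` in length; the default emulates a developing
    drought (0 to +2 deg C with an early +0.2 deg step).  Noise is drawn
    independently per day from seeds derived from config.seed.
    """
    if stress_schedule is None:
        if len(days) != len(DEFAULT_STRESS_SCHEDULE):
            raise ValueError("give a stress_schedule matching the day list")
        stress_schedule = DEFAULT_STRESS_SCHEDULE
    if len(stress_schedule) != len(days):
        raise ValueError(
            f"schedule length {len(stress_schedule)} != number of days {len(days)}"
        )
    geometry_rng = np.random.default_rng(config.seed)
    mix = _plant_geometry(config, geometry_rng)
    scenes: list[DayScene] = []
    for i, (day, stress) in enumerate(zip(days, stress_schedule)):
        day_seed = (config.seed * 1_000_003 + 7919 * (i + 1)) % (2**31)
        day_cfg = replace(config, stress_offset=float(stress), seed=day_seed)
        rng = np.random.default_rng(day_seed)
        cube, tir, truth = _render(day_cfg, mix, rng, day=int(day))
        scenes.append(DayScene(day=int(day), cube=cube, tir=tir, truth=truth))
    return scenes


def write_fixture(scenes: Sequence[DayScene], directory: str | Path,
                  tir_format: str = "csv") -> None:
    """Lay a scene series out on disk exactly as the pipeline readers expect.

    Per day: ``dayNN/hsi.hdr`` + ``dayNN/hsi.raw`` (ENVI pair),
    ``dayNN/tir.csv`` (or ``.tif``), ``dayNN/truth_mask.png``; plus a
    ``manifest.yaml`` echoing the generator configuration.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = scenes[0].truth.config
    manifest = {
        "generator": "thermospec.simulate",
        "seed": int(cfg.seed if len(scenes) == 1 else scenes[0].cube.meta["seed"]),
        "days": [s.day for s in scenes],
        "shape": list(cfg.shape),
        "n_channels": cfg.n_channels,
        "coverage": cfg.coverage,
        "coupled_channels": list(cfg.coupled_channels),
        "beta": cfg.beta,
        "t0": cfg.t0,
        "quantization": cfg.quantization,
        "tir_format": tir_format,
    }
    for scene in scenes:
        sub = directory / f"day{scene.day:02d}"
        sub.mkdir(exist_ok=True)
        tio.write_hsi(scene.cube, sub / "hsi")
        tio.write_tir(scene.tir, sub / f"tir.{tir_format}")
        tio.write_mask(scene.truth.plant_mask(scene.day), sub / "truth_mask.png")
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def load_fixture(directory: str | Path) -> list[tuple[int, HSICube, TIRImage]]:
    """Read back a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    out = []
    for day in manifest["days"]:
        sub = directory / f"day{day:02d}"
        cube = tio.read_hsi(sub / "hsi.hdr")
        tir_file = sub / f"tir.{manifest.get('tir_format', 'csv')}"
        tir = tio.read_tir(tir_file, resolution=manifest.get("quantization") or 0.1)
        out.append((int(day), cube, tir))
    return out


def make_linear_cloud(
    n: int,
    beta: float = -15.0,
    t0: float = 20.0,
    temp_noise_sd: float = 0.1,
    x_range: tuple[float, float] = (0.3, 0.5),
    seed: int = 0,
    channel: int = 143,
    days: Sequence[int] = KEY_DAYS,
):
    """Directly simulated pooled clouds: T = t0 + beta * (x - x0) + noise.

    A shortcut for regression studies that bypasses full scene rendering:
    channel values are uniform on ``x_range`` and temperature is affine in
    the channel plus Gaussian noise, split evenly over ``days``.  Returns
    (list of PointCloud, true slope deg C per unit, true intercept).
    """
    from .types import PointCloud

    rng = np.random.default_rng(seed)
    x0 = 0.5 * (x_range[0] + x_range[1])
    per_day = n // len(days)
    clouds = []
    for i, day in enumerate(days):
        m = per_day if i < len(days) - 1 else n - per_day * (len(days) - 1)
        x = rng.uniform(x_range[0], x_range[1], size=m)
        y = t0 + beta * (x - x0)
        if temp_noise_sd > 0:
            y = y + rng.normal(0.0, temp_noise_sd, size=m)
        clouds.append(
            PointCloud(
                x=x[:, None], y=y,
                rows=np.zeros(m, dtype=int), cols=np.arange(m),
                day=int(day), channels=(channel,),
            )
        )
    return clouds, beta, t0 - beta * x0
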