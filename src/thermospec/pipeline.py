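"""Configuration-driven orchestration of the full study.

One YAML configuration describes where scenes come from (a simulate block
or input files), which thresholds and truncation fractions to sweep,
which channel subsets to evaluate, and the perceptron settings.  A run
produces a directory of CSV reports (day reports, correlation spectra,
extrema, channel-study rows) plus serialised models, every row stamped
with the configuration hash and seed so identical (config, seed) reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import io as tio
from .cloudreg import CloudRegression, day_report
from .correlation import correlation_spectrum, find_extrema, mean_abs_spectrum
from .masking import build_mask, ndblue_map, sample_cloud
from .selection import ChannelSet, extrema_set, full_set, preset_set, range_set
from .simulate import (DEFAULT_STRESS_SCHEDULE, KEY_DAYS, DayScene,
                       SceneConfig, load_fixture, make_timeseries)
from .slp import SLPConfig, TrainReport, assemble_features, train_slp
from .types import PointCloud, ReportTable

logger = logging.getLogger("thermospec")

DEFAULT_CONFIG: dict[str, Any] = {
    "simulate": {
        "shape": [128, 128],
        "n_channels": 204,
        "coverage": 0.35,
        "coupled_channels": [143],
        "days": list(KEY_DAYS),
        "stress_schedule": list(DEFAULT_STRESS_SCHEDULE),
    },
    "inputs": None,
    "thr": [0.3],
    "ab": [[1.0, 1.0], [0.5, 0.5]],
    "channel_sets": [
        {"kind": "extrema", "count": 5},
        {"kind": "full"},
    ],
    "include_day": False,
    "smooth_window": 5,
    "best_channel": None,        # fixed channel for truncation; None = argmax |r|
    "slp": {"max_epochs": 500, "patience": 20, "learning_rate": "auto"},
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """The default run configuration, optionally overridden by a YAML file."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))     # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def validate_config(cfg: dict[str, Any]) -> list[str]:
    """Return a list of problems (empty iff the configuration is runnable)."""
    problems: list[str] = []
    if not cfg.get("simulate") and not cfg.get("inputs"):
        problems.append("one of 'simulate' or 'inputs' must be present")
    thr = cfg.get("thr") or []
    if not thr:
        problems.append("thr: list must be non-empty")
    for t in thr:
        if not isinstance(t, (int, float)) or not 0.0 <= t <= 1.0:
            problems.append(f"thr: value {t!r} outside [0, 1] (study range 0.1-0.5)")
    ab = cfg.get("ab") or []
    if not ab:
        problems.append("ab: list must be non-empty")
    for pair in ab:
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            problems.append(f"ab: entry {pair!r} must be a [a, b] pair")
            continue
        a, b = pair
        if not 0.0 <= a <= 1.0:
            problems.append(f"a: value {a!r} must lie in [0, 1]")
        if not 0.0 <= b <= 1.0:
            problems.append(f"b: value {b!r} must lie in [0, 1]")
    if not cfg.get("channel_sets"):
        problems.append("channel_sets: list must be non-empty")
    sw = cfg.get("smooth_window", 5)
    if not (isinstance(sw, int) and sw >= 1 and sw % 2 == 1):
        problems.append(f"smooth_window: {sw!r} must be a positive odd integer")
    slp = cfg.get("slp", {})
    if slp.get("max_epochs", 1) < 1:
        problems.append("slp.max_epochs: must be >= 1")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed: {seed!r} must be an integer")
    sim = cfg.get("simulate")
    if sim:
        days = sim.get("days", list(KEY_DAYS))
        sched = sim.get("stress_schedule", list(DEFAULT_STRESS_SCHEDULE))
        if len(days) != len(sched):
            problems.append("simulate.stress_schedule: length must match simulate.days")
    return problems


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a configuration (canonical JSON, sha256/12)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed derived from the run seed by a fixed stage-name hash."""
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _load_scenes(cfg: dict[str, Any]) -> list[DayScene]:
    if cfg.get("inputs"):
        inputs = cfg["inputs"]
        if isinstance(inputs, str):
            loaded = load_fixture(inputs)
            return [
                DayScene(day=d, cube=c, tir=t, truth=None) for d, c, t in loaded
            ]
        scenes = []
        for entry in inputs:
            cube = tio.read_hsi(entry["hsi"])
            tir = tio.read_tir(entry["tir"], resolution=entry.get("resolution", 0.1))
            scenes.append(DayScene(day=int(entry["day"]), cube=cube, tir=tir, truth=None))
        return scenes
    sim = dict(cfg["simulate"])
    days = sim.pop("days", list(KEY_DAYS))
    schedule = sim.pop("stress_schedule", None)
    sim["shape"] = tuple(sim.get("shape", (128, 128)))
    sim["coupled_channels"] = tuple(sim.get("coupled_channels", (143,)))
    scfg = SceneConfig(**sim, seed=stage_seed(cfg["seed"], "simulate"))
    return make_timeseries(scfg, stress_schedule=schedule, days=days)


def _resolve_sets(
    specs: Sequence[dict[str, Any]], n_channels: int, spectra, smooth_window: int
) -> list[ChannelSet]:
    sets = []
    for spec in specs:
        kind = spec.get("kind", "explicit")
        if kind == "full":
            sets.append(full_set(n_channels))
        elif kind == "range":
            sets.append(range_set(int(spec["lo"]), int(spec["hi"])))
        elif kind == "extrema":
            sets.append(
                extrema_set(spectra, smooth_window=spec.get("smooth_window", smooth_window),
                            count=spec.get("count"))
            )
        elif kind == "preset":
            sets.append(preset_set(spec["name"]))
        elif kind == "explicit":
            sets.append(ChannelSet(tuple(spec["channels"]), "explicit",
                                   spec.get("label", "")))
        else:
            raise ValueError(f"unknown channel-set kind {kind!r}")
    return sets


def _split_cloud(cloud: PointCloud, rng: np.random.Generator) -> tuple[PointCloud, PointCloud]:
    """Seeded half/half row split into train and test clouds."""
    perm = rng.permutation(cloud.n)
    half = cloud.n // 2
    return cloud.subset(np.sort(perm[half:])), cloud.subset(np.sort(perm[:half]))


def run_pipeline(cfg: dict[str, Any], out: str | Path) -> Path:
    """Execute the full study for every parameter combination in ``cfg``.

    Writes day_report.csv, train_report.csv, per-day and mean correlation
    spectra, extrema lists, serialised models and a run log under ``out``.
    Stage failures abort that parameter combination, are logged, and are
    summarised at exit; any failure raises after the sweep completes.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.perf_counter()
    failures: list[str] = []
    stamp = {"config_hash": chash, "seed": seed}

    try:
        scenes = _load_scenes(cfg)
        logger.info("loaded %d scenes, raster %s, K=%d",
                    len(scenes), scenes[0].cube.shape, scenes[0].cube.n_channels)
        k_total = scenes[0].cube.n_channels
        all_channels = list(range(k_total))
        smooth_window = int(cfg.get("smooth_window", 5))
        slp_cfg_base = dict(cfg.get("slp", {}))

        day_rows = ReportTable("day_report")
        train_rows = ReportTable("train_report")
        (out / "spectra").mkdir(exist_ok=True)
        (out / "models").mkdir(exist_ok=True)

        for thr in cfg["thr"]:
            combo = f"thr={thr}"
            try:
                t0 = time.perf_counter()
                spectra = []
                masks = {}
                for scene in scenes:
                    index = ndblue_map(scene.cube)
                    mask = build_mask(index, thr, day=scene.day)
                    masks[scene.day] = (index, mask)
                    spec = correlation_spectrum(scene.cube, scene.tir, mask)
                    spectra.append(spec)
                    tbl = ReportTable("spectrum")
                    tbl.extend(spec.to_frame().to_dict("records"))
                    tio.write_report(
                        tbl, out / "spectra" / f"thr{thr}_day{scene.day:02d}.csv",
                        extra={**stamp, "stage": "correlate"},
                    )
                    logger.info("%s day %d: mask %d px, cloud %d",
                                combo, scene.day, mask.area, spec.n)
                mean_spec = mean_abs_spectrum(spectra)
                tbl = ReportTable("spectrum")
                tbl.extend(mean_spec.to_frame().to_dict("records"))
                tio.write_report(tbl, out / "spectra" / f"thr{thr}_mean.csv",
                                 extra={**stamp, "stage": "correlate"})
                extrema = find_extrema(mean_spec, smooth_window=smooth_window)
                etbl = ReportTable("extrema")
                for ch, kind in extrema:
                    etbl.append({"channel": ch,
                                 "wavelength_nm": scenes[0].cube.wavelength_of(ch),
                                 "kind": kind})
                tio.write_report(etbl, out / "spectra" / f"thr{thr}_extrema.csv",
                                 extra={**stamp, "stage": "correlate"})
                logger.info("%s: %d extrema on mean |r| curve", combo, len(extrema))

                channel_sets = _resolve_sets(
                    cfg["channel_sets"], k_total, mean_spec, smooth_window
                )
                best_fixed = cfg.get("best_channel")
                trunc_channel = (int(best_fixed) if best_fixed is not None
                                 else mean_spec.best_channel())

                for a, b in cfg["ab"]:
                    combo_ab = f"{combo} a={a} b={b}"
                    try:
                        for scene in scenes:
                            index, _ = masks[scene.day]
                            row = day_report(scene.cube, scene.tir, index,
                                             scene.day, thr, a, b)
                            day_rows.append(row)
                        # kept clouds for SLP training: truncate against the
                        # study channel's moment line per day
                        rng = np.random.default_rng(stage_seed(seed, f"split:{combo_ab}"))
                        train_clouds, test_clouds = [], []
                        for scene in scenes:
                            _, mask = masks[scene.day]
                            cloud = sample_cloud(scene.cube, scene.tir, mask, all_channels)
                            fit = CloudRegression(cloud, channel=trunc_channel).fit()
                            kept = fit.truncate(a, b).kept
                            tr, te = _split_cloud(kept, rng)
                            train_clouds.append(tr)
                            test_clouds.append(te)
                        n_train = sum(c.n for c in train_clouds)
                        n_test = sum(c.n for c in test_clouds)
                        logger.info("%s: train %d px, test %d px", combo_ab, n_train, n_test)
                        for cs in channel_sets:
                            cs.validate(k_total)
                            slp_cfg = SLPConfig(
                                **slp_cfg_base,
                                seed=stage_seed(seed, f"slp:{combo_ab}:{cs.label}"),
                            )
                            train_fm = assemble_features(
                                train_clouds, cs.channels, cfg.get("include_day", False)
                            )
                            test_fm = assemble_features(
                                test_clouds, cs.channels, cfg.get("include_day", False)
                            )
                            model = train_slp(train_fm, test_fm, slp_cfg)
                            tr_rmse, _ = model.evaluate(train_fm)
                            te_rmse, _ = model.evaluate(test_fm)
                            rep = TrainReport(
                                label=cs.label, k=cs.k, thr=thr, a=a, b=b,
                                train_mask_pix=n_train, test_mask_pix=n_test,
                                train_rmse_c=tr_rmse, test_rmse_c=te_rmse,
                                epochs=model.epochs_run,
                                wall_seconds=model.wall_seconds,
                            )
                            train_rows.append(rep.as_row())
                            safe = cs.label.replace(" ", "").replace("(", "").replace(")", "")
                            model.to_json(
                                out / "models" / f"thr{thr}_a{a}_b{b}_{safe}.json"
                            )
                            logger.info(
                                "%s set %s: train RMSE %.3f C, test RMSE %.3f C, "
                                "%d epochs (%.1f s)",
                                combo_ab, cs.label, tr_rmse, te_rmse,
                                model.epochs_run, model.wall_seconds,
                            )
                    except Exception as exc:          # combination-level abort
                        failures.append(f"{combo_ab}: {exc}")
                        logger.error("%s failed: %s", combo_ab, exc)
                logger.info("%s done in %.1f s", combo, time.perf_counter() - t0)
            except Exception as exc:
                failures.append(f"{combo}: {exc}")
                logger.error("%s failed: %s", combo, exc)

        tio.write_report(day_rows, out / "day_report.csv",
                         extra={**stamp, "stage": "report-day"})
        tio.write_report(train_rows, out / "train_report.csv",
                         extra={**stamp, "stage": "train"})
        logger.info("pipeline finished in %.1f s, %d failure(s)",
                    time.perf_counter() - t_start, len(failures))
    finally:
        logger.removeHandler(handler)
        handler.close()

    if failures:
        raise RuntimeError(
            f"{len(failures)} parameter combination(s) failed: " + "; ".join(failures)
        )
    return out
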