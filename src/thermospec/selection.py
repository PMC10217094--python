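"""Channel-subset construction and the nested channel-reduction study.

The study asks how far the feature set can shrink — from the full
spectrum, through the low-noise contiguous range, to a handful of
correlation-extrema channels — while temperature-prediction RMSE stays
essentially flat.  Subsets are evaluated, not searched: candidate lists
come from the correlation spectrum's extrema, from the user, or from the
shipped named presets, and each is trained and scored with the same
perceptron configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .correlation import CorrelationSpectrum, find_extrema, mean_abs_spectrum
from .slp import FeatureMatrix, SLPConfig, SLPRegressor, TrainReport, assemble_features
from .types import PointCloud, ReportTable

# Channel presets from the published 204-band study (Specim IQ numbering,
# 0-based): the 32 correlation-curve extrema, the 8-channel mixture of
# extrema and agronomy-standard bands, and its 7-channel refinement
# (channel 95 removed).  Printed lists; not derivable from data.
PRESETS: dict[str, tuple[int, ...]] = {
    "paper-32": (9, 12, 14, 22, 25, 28, 36, 47, 56, 59, 71, 75, 82, 85, 88, 90,
                 95, 108, 111, 116, 120, 122, 126, 131, 133, 136, 139, 143, 150,
                 153, 157, 160),
    "paper-8": (95, 116, 126, 136, 143, 153, 157, 160),
    "paper-7": (116, 126, 136, 143, 153, 157, 160),
}


@dataclass(frozen=True)
class ChannelSet:
    """An ordered set of 0-based channel indices with provenance and a label."""

    channels: tuple[int, ...]
    provenance: str = "explicit"      # full | contiguous-range | plcc-extrema | curated | explicit
    label: str = ""

    def __post_init__(self) -> None:
        chans = tuple(sorted(set(int(c) for c in self.channels)))
        if not chans:
            raise ValueError("channel set must be non-empty")
        if chans[0] < 0:
            raise ValueError("channel indices must be non-negative")
        object.__setattr__(self, "channels", chans)
        if not self.label:
            object.__setattr__(self, "label", f"{len(chans)}ch")

    @property
    def k(self) -> int:
        return len(self.channels)

    def validate(self, n_channels: int) -> None:
        if self.channels[-1] >= n_channels:
            raise IndexError(
                f"channel {self.channels[-1]} out of range for a {n_channels}-band cube"
            )


def full_set(n_channels: int) -> ChannelSet:
    return ChannelSet(tuple(range(n_channels)), "full", f"{n_channels} (full)")


def range_set(lo: int, hi: int) -> ChannelSet:
    """Contiguous channels lo..hi inclusive (e.g. 15-160 -> 146 channels)."""
    if hi < lo:
        raise ValueError(f"empty range {lo}..{hi}")
    return ChannelSet(tuple(range(lo, hi + 1)), "contiguous-range", f"{hi - lo + 1} ({lo}-{hi})")


def extrema_set(
    spectra: Sequence[CorrelationSpectrum] | CorrelationSpectrum,
    smooth_window: int = 5,
    count: int | None = None,
) -> ChannelSet:
    """Correlation-extrema channels, ranked by day-averaged |r|.

    ``spectra`` is a single spectrum or per-day list (averaged as mean |r|);
    the extrema of the smoothed curve are ranked by their |r| value on the
    averaged spectrum and the best ``count`` kept (all, if None).
    """
    if isinstance(spectra, CorrelationSpectrum):
        mean = spectra
    else:
        mean = mean_abs_spectrum(list(spectra))
    candidates = find_extrema(mean, smooth_window=smooth_window)
    if not candidates:
        raise ValueError("correlation curve has no interior extrema")
    ranked = sorted(candidates, key=lambda ce: (-abs(mean.r[ce[0]]), ce[0]))
    if count is not None:
        if count < 1:
            raise ValueError("count must be >= 1")
        ranked = ranked[:count]
    chans = tuple(c for c, _ in ranked)
    return ChannelSet(chans, "plcc-extrema", f"{len(chans)} (extrema)")


def preset_set(name: str) -> ChannelSet:
    try:
        chans = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
    return ChannelSet(chans, "curated", name)


def make_subset(kind: str, **kwargs) -> ChannelSet:
    """Uniform constructor: kind in {full, range, extrema, explicit, preset}.

    full:     n_channels=K
    range:    lo=, hi=  (inclusive)
    extrema:  spectra=, smooth_window=5, count=None
    explicit: channels=[...]
    preset:   name="paper-32" | "paper-8" | "paper-7"
    """
    if kind == "full":
        return full_set(kwargs["n_channels"])
    if kind == "range":
        return range_set(kwargs["lo"], kwargs["hi"])
    if kind == "extrema":
        return extrema_set(
            kwargs["spectra"],
            smooth_window=kwargs.get("smooth_window", 5),
            count=kwargs.get("count"),
        )
    if kind == "explicit":
        return ChannelSet(tuple(kwargs["channels"]), "explicit",
                          kwargs.get("label", ""))
    if kind == "preset":
        return preset_set(kwargs["name"])
    raise ValueError(f"unknown subset kind {kind!r}")


def evaluate_subset(
    channel_set: ChannelSet,
    train_clouds: Sequence[PointCloud],
    test_clouds: Sequence[PointCloud],
    config: SLPConfig | None = None,
    include_day: bool = False,
    thr: float = float("nan"),
    a: float = 1.0,
    b: float = 1.0,
) -> TrainReport:
    """Train the perceptron on one channel subset and score train/test RMSE.

    The clouds must have been sampled with (at least) the subset's
    channels; mask pixel counts in the report depend only on (thr, a, b),
    never on the subset.
    """
    train_fm = assemble_features(train_clouds, channel_set.channels, include_day)
    test_fm = (
        assemble_features(test_clouds, channel_set.channels, include_day)
        if test_clouds else None
    )
    model = SLPRegressor(train_fm, test_fm, config).fit()
    train_rmse, _ = model.evaluate(train_fm)
    if test_fm is not None:
        test_rmse, _ = model.evaluate(test_fm)
        test_pix = test_fm.n
    else:
        test_rmse, test_pix = float("nan"), 0
    return TrainReport(
        label=channel_set.label,
        k=channel_set.k,
        thr=thr, a=a, b=b,
        train_mask_pix=sum(c.n for c in train_clouds),
        test_mask_pix=test_pix,
        train_rmse_c=train_rmse,
        test_rmse_c=test_rmse,
        epochs=model.epochs_run,
        wall_seconds=model.wall_seconds,
    )


def reduction_study(
    sets: Sequence[ChannelSet],
    train_clouds: Sequence[PointCloud],
    test_clouds: Sequence[PointCloud],
    config: SLPConfig | None = None,
    include_day: bool = False,
    thr: float = float("nan"),
    a: float = 1.0,
    b: float = 1.0,
) -> ReportTable:
    """Evaluate every channel set on the same clouds; one report row per set, in order."""
    if not sets:
        raise ValueError("need at least one channel set")
    table = ReportTable("train_report")
    for cs in sets:
        rep = evaluate_subset(
            cs, train_clouds, test_clouds, config,
            include_day=include_day, thr=thr, a=a, b=b,
        )
        table.append(rep.as_row())
    return table
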