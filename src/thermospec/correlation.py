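"""Per-channel Pearson correlation between hyperspectral bands and temperature.

For a fixed plant mask, every hyperspectral channel yields a paired sample
(channel value, temperature) over the mask pixels; the Pearson linear
correlation coefficient (PLCC)

    r(x, y) = cov(x, y) / (sigma_x * sigma_y)

scanned over all K channels forms a correlation spectrum whose extrema
are the natural candidates for temperature-informative bands.  Spectra
from several key days are combined as the per-channel mean of |r| —
late-stress days can be anti-correlated, so averaging signed r would
cancel real signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import HSICube, PlantMask, TIRImage, UndefinedCorrelationError


@dataclass
class CorrelationSpectrum:
    """PLCC per channel under one mask/cloud parameterisation.

    ``r`` has one entry per channel; channels whose values had zero
    variance under the mask carry NaN (undefined correlation, flagged not
    silently zeroed).  ``day`` is the key-day ordinal or ``"mean"`` for a
    day-averaged absolute spectrum.
    """

    r: np.ndarray
    wavelengths: np.ndarray
    day: int | str
    thr: float = float("nan")
    a: float = 1.0
    b: float = 1.0
    n: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.r.shape != self.wavelengths.shape:
            raise ValueError("r and wavelengths must have one entry per channel")
        finite = self.r[np.isfinite(self.r)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("PLCC values must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return self.r.size

    def best_channel(self) -> int:
        """Channel index maximising |r| (NaN entries ignored)."""
        return int(np.nanargmax(np.abs(self.r)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"channel": np.arange(self.n_channels),
             "wavelength_nm": self.wavelengths,
             "r": self.r}
        )


def plcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson linear correlation coefficient of two equal-length sequences.

    Population moments are used throughout (the n vs n-1 convention cancels
    in the ratio anyway).  Zero variance in either argument raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc * xc))
    sy = np.sqrt(np.mean(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(np.mean(xc * yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


def correlation_spectrum(
    cube: HSICube, tir: TIRImage, mask: PlantMask
) -> CorrelationSpectrum:
    """PLCC of every channel against temperature under ``mask``.

    Vectorised over channels; channels with zero variance under the mask
    get NaN entries.  Missing TIR pixels are dropped from the sample.
    """
    if cube.shape != tir.shape or cube.shape != mask.shape:
        raise ValueError("cube, tir and mask must share one raster grid")
    rows, cols = np.nonzero(mask.member)
    y = tir.values[rows, cols]
    ok = ~np.isnan(y)
    rows, cols, y = rows[ok], cols[ok], y[ok]
    n = y.size
    if n < 2:
        raise ValueError(f"mask holds {n} usable pixels; need >= 2 for correlation")
    x = cube.values[:, rows, cols].astype(np.float64)     # (K, n)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc * xc, axis=1))
    sy = np.sqrt(np.mean(yc * yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / n / (sx * sy)
    r[sx == 0.0] = np.nan
    if sy == 0.0:
        r[:] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return CorrelationSpectrum(
        r=r, wavelengths=cube.wavelengths.copy(), day=mask.day, thr=mask.thr, n=int(n)
    )


def mean_abs_spectrum(spectra: Sequence[CorrelationSpectrum]) -> CorrelationSpectrum:
    """Per-channel arithmetic mean of |r| across days, tagged day='mean'."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum to average")
    k = spectra[0].n_channels

    def same(u: float, v: float) -> bool:
        return u == v or (np.isnan(u) and np.isnan(v))

    first = spectra[0]
    for s in spectra:
        if s.n_channels != k:
            raise ValueError("all spectra must share the channel count")
        if not (same(s.thr, first.thr) and same(s.a, first.a) and same(s.b, first.b)):
            raise ValueError("all spectra must share the (thr, a, b) parameter tuple")
    stack = np.vstack([np.abs(s.r) for s in spectra])
    return CorrelationSpectrum(
        r=np.nanmean(stack, axis=0),
        wavelengths=spectra[0].wavelengths.copy(),
        day="mean",
        thr=spectra[0].thr,
        a=spectra[0].a,
        b=spectra[0].b,
        n=int(sum(s.n for s in spectra)),
    )


def find_extrema(
    spectrum: CorrelationSpectrum, smooth_window: int = 5
) -> list[tuple[int, str]]:
    """Local extrema of the (optionally smoothed) |r| curve.

    The curve is smoothed with a centred rectangular moving average of odd
    width ``smooth_window`` (1 = no smoothing; reflect-padded at the ends)
    and extrema are located by strict comparison against both neighbours.
    A plateau strictly above (below) its flanks counts once, at its lowest
    channel index.  Each extremum found on the smoothed curve is then
    snapped to the extremum of the *raw* |r| curve within half a window —
    extrema are detected on the smoothed curve but reported at original
    channel indices, so a single-channel spike widened into a plateau by
    the averaging still reports the spike's own channel.  Endpoints are
    never reported.  Returns ``(channel, 'max'|'min')`` pairs in channel
    order.
    """
    k = spectrum.n_channels
    if k < 3:
        raise ValueError("need at least 3 channels to find interior extrema")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if smooth_window >= k:
        raise ValueError(f"smooth_window {smooth_window} must be < number of channels {k}")
    raw = np.abs(np.nan_to_num(spectrum.r, nan=0.0))
    pad = smooth_window // 2
    if smooth_window > 1:
        padded = np.pad(raw, pad, mode="reflect")
        kernel = np.ones(smooth_window) / smooth_window
        curve = np.convolve(padded, kernel, mode="valid")
    else:
        curve = raw

    found: list[tuple[int, str]] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and curve[j + 1] == curve[i]:
            j += 1
        # run [i, j] of equal values; interior extremum iff both flanks exist
        if i > 0 and j < k - 1:
            left, right = curve[i - 1], curve[j + 1]
            if curve[i] > left and curve[i] > right:
                found.append((i, "max"))
            elif curve[i] < left and curve[i] < right:
                found.append((i, "min"))
        i = j + 1

    out: list[tuple[int, str]] = []
    seen: set[int] = set()
    for idx, kind in found:
        lo = max(1, idx - pad)
        hi = min(k - 1, idx + pad + 1)
        window = raw[lo:hi]
        snapped = lo + int(np.argmax(window) if kind == "max" else np.argmin(window))
        if snapped not in seen:
            seen.add(snapped)
            out.append((snapped, kind))
    out.sort(key=lambda ck: ck[0])
    return out
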