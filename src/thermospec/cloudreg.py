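"""Single-channel temperature regression on a point cloud, with truncation.

The predictor is the moment line

    y(x) = Ey + s * (sigma_y / sigma_x) * (x - Ex),    s = sign of r(x, y),

the standardised (reduced) major-axis line through the cloud's centroid.
The slope magnitude is the ratio of standard deviations, so the line is
exact on any noiseless affine cloud; the sign factor makes it track
anti-correlated clouds (late-stress days can have negative PLCC) with the
correct orientation.  ``signed_slope=False`` gives the literal unsigned
sigma-ratio slope.

Truncation removes cloud points deviating from the fitted line by more
than a fraction ``a`` of the largest upward residual or ``b`` of the
largest downward residual; a = b = 1 keeps everything.  This trims the
heteroscedastic fringe of the cloud (mixed leaf/soil boundary pixels) and
is reported as "mask in" (kept) vs "out" (removed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .correlation import correlation_spectrum, plcc
from .masking import build_mask, sample_cloud
from .types import HSICube, IndexMap, PointCloud, TIRImage


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root-mean-square error in deg C between two equal-length sequences."""
    predicted = np.asarray(predicted, dtype=np.float64).ravel()
    actual = np.asarray(actual, dtype=np.float64).ravel()
    if predicted.size != actual.size:
        raise ValueError(f"length mismatch: {predicted.size} vs {actual.size}")
    if predicted.size == 0:
        raise ValueError("RMSE of an empty sequence is undefined")
    d = predicted - actual
    return float(np.sqrt(np.mean(d * d)))


class CloudRegression:
    """Moment-line temperature model for a single-channel point cloud.

    Parameters
    ----------
    cloud : PointCloud
        Paired (channel value, temperature) records; must expose exactly
        one channel (or name one via ``channel``).
    channel : int, optional
        Which sampled channel to regress on if the cloud holds several.
    signed_slope : bool
        Multiply the sigma-ratio slope by the sign of the Pearson
        correlation (default) instead of using the literal unsigned form.
    """

    def __init__(
        self,
        cloud: PointCloud,
        channel: int | None = None,
        signed_slope: bool = True,
    ) -> None:
        self.cloud = cloud
        self.channel = int(channel) if channel is not None else (
            cloud.channels[0] if cloud.k == 1 else None
        )
        if self.channel is None:
            raise ValueError("cloud holds several channels; pass channel=")
        self.signed_slope = signed_slope
        self._x = cloud.single_channel(self.channel)
        self._y = cloud.y

    def fit(self) -> "CloudRegressionResults":
        x, y = self._x, self._y
        if x.size < 2:
            raise ValueError(f"cloud of size {x.size} is too small to fit (need >= 2)")
        ex, ey = float(x.mean()), float(y.mean())
        sx = float(np.sqrt(np.mean((x - ex) ** 2)))
        sy = float(np.sqrt(np.mean((y - ey) ** 2)))
        if sx == 0.0:
            raise ValueError("channel values are constant; predictor undefined")
        if sy == 0.0:
            r = 0.0          # flat temperature: slope magnitude is 0, sign moot
            sign = 1
        else:
            r = plcc(x, y)
            sign = 1 if r >= 0 else -1
        if not self.signed_slope:
            sign = 1
        return CloudRegressionResults(
            model=self, ex=ex, ey=ey, sx=sx, sy=sy, sign=sign, plcc=r, n=int(x.size)
        )


@dataclass
class CloudRegressionResults:
    """Fitted moment line: parameters, diagnostics, prediction and truncation."""

    model: CloudRegression
    ex: float
    ey: float
    sx: float
    sy: float
    sign: int
    plcc: float
    n: int

    @property
    def slope(self) -> float:
        """deg C per channel unit."""
        return self.sign * self.sy / self.sx

    @property
    def intercept(self) -> float:
        return self.ey - self.slope * self.ex

    def predict(self, x) -> np.ndarray | float:
        """Temperature prediction; scalar in, scalar out."""
        x_arr = np.asarray(x, dtype=np.float64)
        out = self.ey + self.slope * (x_arr - self.ex)
        return float(out) if np.isscalar(x) or out.ndim == 0 else out

    def resid(self, cloud: PointCloud | None = None) -> np.ndarray:
        """Residuals y - y(x) on ``cloud`` (default: the training cloud)."""
        if cloud is None:
            x, y = self.model._x, self.model._y
        else:
            x, y = cloud.single_channel(self.model.channel), cloud.y
        return y - self.predict(x)

    def rmse(self, cloud: PointCloud | None = None) -> float:
        r = self.resid(cloud)
        if r.size == 0:
            raise ValueError("RMSE of an empty cloud is undefined")
        return float(np.sqrt(np.mean(r * r)))

    def truncate(self, a: float, b: float) -> "TruncationResult":
        """Split the training cloud by residual against this fitted line.

        ``threshold_up = a * max(positive residuals)`` and
        ``threshold_down = b * |min(negative residuals)|``; a record is
        kept iff ``-threshold_down <= resid <= threshold_up``.  Single
        pass: the line is not refitted inside the truncation.  a = b = 1
        keeps the whole cloud.
        """
        a, b = float(a), float(b)
        if not (0.0 <= a <= 1.0) or not (0.0 <= b <= 1.0):
            raise ValueError(f"a and b must lie in [0, 1], got a={a}, b={b}")
        r = self.resid()
        pos = r[r > 0]
        neg = r[r < 0]
        threshold_up = a * float(pos.max()) if pos.size else 0.0
        threshold_down = b * float(-neg.min()) if neg.size else 0.0
        keep = (r >= -threshold_down) & (r <= threshold_up)
        cloud = self.model.cloud
        return TruncationResult(
            kept=cloud.subset(keep),
            removed=cloud.subset(~keep),
            a=a, b=b,
            threshold_up=threshold_up,
            threshold_down=threshold_down,
        )

    def summary(self) -> str:
        lines = [
            "Cloud regression (moment line)",
            "------------------------------",
            f"channel           {self.model.channel}",
            f"n                 {self.n}",
            f"Ex, Ey            {self.ex:.6g}, {self.ey:.6g} degC",
            f"sigma_x, sigma_y  {self.sx:.6g}, {self.sy:.6g}",
            f"sign(PLCC)        {self.sign:+d}",
            f"PLCC              {self.plcc:.4f}",
            f"slope             {self.slope:.6g} degC/unit",
            f"intercept         {self.intercept:.6g} degC",
            f"train RMSE        {self.rmse():.4g} degC",
        ]
        return "\n".join(lines)


@dataclass
class TruncationResult:
    """Kept ("mask in") vs removed ("out") partition of a cloud, with the cutoffs applied."""

    kept: PointCloud
    removed: PointCloud
    a: float
    b: float
    threshold_up: float
    threshold_down: float

    @property
    def n_kept(self) -> int:
        return self.kept.n

    @property
    def n_removed(self) -> int:
        return self.removed.n


def fit_predictor(
    cloud: PointCloud, channel: int | None = None, signed_slope: bool = True
) -> CloudRegressionResults:
    """Convenience wrapper: fit the moment-line predictor on a cloud."""
    return CloudRegression(cloud, channel=channel, signed_slope=signed_slope).fit()


def truncate_cloud(
    cloud: PointCloud, results: CloudRegressionResults, a: float, b: float
) -> TruncationResult:
    """Truncate ``cloud`` against an already-fitted line (see Results.truncate)."""
    if cloud is not results.model.cloud:
        refit = CloudRegression(cloud, channel=results.model.channel,
                                signed_slope=results.model.signed_slope)
        tmp = CloudRegressionResults(
            model=refit, ex=results.ex, ey=results.ey, sx=results.sx,
            sy=results.sy, sign=results.sign, plcc=results.plcc, n=cloud.n,
        )
        return tmp.truncate(a, b)
    return results.truncate(a, b)


def day_report(
    cube: HSICube,
    tir: TIRImage,
    index: IndexMap,
    day: int,
    thr: float,
    a: float,
    b: float,
    channel: int | None = None,
    signed_slope: bool = True,
) -> dict[str, Any]:
    """One study row for a (day, thr, a, b) parameter tuple.

    Builds the mask, scans the correlation spectrum, picks the best channel
    by max |r| (unless ``channel`` is given), fits the moment line,
    truncates with (a, b), refits on the kept records and reports mask
    area, PLCC (full and kept), best channel + wavelength, full-cloud RMSE,
    RMSE-in on the kept records and RMSE-out on the removed records (both
    evaluated with the kept-records refit).
    """
    mask = build_mask(index, thr, day)
    spectrum = correlation_spectrum(cube, tir, mask)
    best = int(channel) if channel is not None else spectrum.best_channel()
    cloud = sample_cloud(cube, tir, mask, [best])
    full_fit = CloudRegression(cloud, signed_slope=signed_slope).fit()
    rmse_full = full_fit.rmse()
    trunc = full_fit.truncate(a, b)

    if trunc.n_removed == 0:
        rmse_in = rmse_full
        plcc_in = full_fit.plcc
        rmse_out = float("nan")
        kept_n = cloud.n
    else:
        kept_fit = CloudRegression(trunc.kept, signed_slope=signed_slope).fit()
        rmse_in = kept_fit.rmse()
        plcc_in = kept_fit.plcc
        rmse_out = kept_fit.rmse(trunc.removed)
        kept_n = trunc.n_kept

    return {
        "day": day,
        "thr": thr,
        "a": a,
        "b": b,
        "mask_pix": mask.area,
        "cloud_n": cloud.n,
        "plcc": full_fit.plcc,
        "best_channel": best,
        "wavelength_nm": cube.wavelength_of(best),
        "rmse_c": rmse_full,
        "mask_in_pix": kept_n,
        "plcc_in": plcc_in,
        "rmse_in_c": rmse_in,
        "rmse_out_c": rmse_out,
    }
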