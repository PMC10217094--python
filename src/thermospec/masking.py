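"""NDblue plant masking and masked pixel sampling.

Plant pixels are separated from soil with the NDblue vegetation index

    V = R550 - R450,    NDblue = V / (max V - min V),

where the max/min are taken over a normalisation region (the whole image
by default).  A pixel belongs to the plant mask when NDblue >= thr; the
threshold controls how much soil admixture is tolerated in a "plant"
pixel.  Healthy leaf tissue reflects far more at 550 nm (green peak) than
at 450 nm, while soil is nearly flat across that pair, so V separates the
two materials.
"""

from __future__ import annotations

import numpy as np

from .types import DegenerateImageError, HSICube, IndexMap, PlantMask, PointCloud, TIRImage


def ndblue_map(cube: HSICube, region: np.ndarray | None = None) -> IndexMap:
    """Per-pixel NDblue = V / (max V - min V) with V = R550 - R450.

    The 450 and 550 nm bands are located with :meth:`HSICube.channel_near`.
    ``region`` optionally restricts where max V / min V are taken (the
    normalisation is a scene statistic; per-pot analysis can pass the pot's
    bounding mask) — the index itself is still evaluated everywhere.
    """
    lo, hi = cube.wavelengths[0], cube.wavelengths[-1]
    if not (lo <= 450 <= hi) or not (lo <= 550 <= hi):
        raise ValueError(
            f"cube covers {lo:.0f}-{hi:.0f} nm; NDblue needs both 450 and 550 nm"
        )
    r550 = cube.band(cube.channel_near(550.0)).astype(np.float64)
    r450 = cube.band(cube.channel_near(450.0)).astype(np.float64)
    v = r550 - r450
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != v.shape:
            raise ValueError("normalisation region shape must match the raster")
        if not region.any():
            raise ValueError("normalisation region is empty")
        v_region = v[region]
    else:
        v_region = v
    v_min = float(v_region.min())
    v_max = float(v_region.max())
    if v_max == v_min:
        raise DegenerateImageError(
            "V = R550 - R450 is constant over the normalisation region; NDblue undefined"
        )
    return IndexMap(values=v / (v_max - v_min), v_min=v_min, v_max=v_max)


def build_mask(index: IndexMap, thr: float, day: int = 0) -> PlantMask:
    """Threshold an NDblue map: member iff NDblue >= thr (study range 0.1-0.5)."""
    thr = float(thr)
    if not np.isfinite(thr):
        raise ValueError("thr must be finite")
    return PlantMask(member=index.values >= thr, thr=thr, day=day)


def sample_cloud(
    cube: HSICube,
    tir: TIRImage,
    mask: PlantMask,
    channels: list[int] | tuple[int, ...],
) -> PointCloud:
    """Collect the (channel values, temperature) cloud under a plant mask.

    The cube, the (already warped) TIR raster and the mask must share one
    pixel grid.  Records whose TIR value is missing are dropped and counted
    in ``n_missing``.  The sampling is a pure projection: rerunning it on
    the same inputs yields identical records (row-major pixel order).
    """
    if cube.shape != tir.shape or cube.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: cube {cube.shape}, tir {tir.shape}, mask {mask.shape}"
        )
    channels = [int(c) for c in channels]
    for c in channels:
        if not 0 <= c < cube.n_channels:
            raise IndexError(f"channel {c} out of range [0, {cube.n_channels})")
    rows, cols = np.nonzero(mask.member)
    y = tir.values[rows, cols]
    ok = ~np.isnan(y)
    n_missing = int((~ok).sum())
    rows, cols, y = rows[ok], cols[ok], y[ok]
    x = cube.values[np.asarray(channels)][:, rows, cols].T.astype(np.float64)
    return PointCloud(
        x=x, y=y, rows=rows, cols=cols, day=mask.day,
        channels=tuple(channels), n_missing=n_missing,
    )
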