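"""Homography alignment of TIR rasters onto the HSI pixel grid.

The two cameras view the same pot from slightly different geometry and at
different resolutions (e.g. 512x512 hyperspectral vs 320x240 thermal), so
paired analysis first maps the temperature raster onto the hyperspectral
grid with a projective transform fitted to user-supplied control points.

Coordinates are (row, col) from the top-left corner throughout; the
homography matrix acts on homogeneous (row, col, 1) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import estimate_transform

from .types import TIRImage


@dataclass(frozen=True)
class Homography:
    """A 3x3 projective transform, normalised so the bottom-right entry is 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(m[2, 2]) < 1e-15:
            raise ValueError("homography bottom-right entry must be non-zero")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography matrix is singular")
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) (row, col) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))


def fit_homography(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Least-squares projective transform mapping src (row, col) points onto dst.

    Uses the normalised direct linear transform.  At least 4 correspondences
    are required and they must not be collinear.
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must both be (n, 2) point lists")
    if src.shape[0] < 4:
        raise ValueError(f"homography needs >= 4 correspondences, got {src.shape[0]}")
    if _collinear(src) or _collinear(dst):
        raise ValueError("degenerate control points: all (nearly) collinear")
    # skimage's DLT is coordinate-convention agnostic; we feed (row, col)
    # as its 2-D coordinates so the matrix acts on (row, col, 1) directly.
    tform = estimate_transform("projective", src, dst)
    m = np.asarray(tform.params)
    if not np.all(np.isfinite(m)):
        raise ValueError("homography fit failed (degenerate configuration)")
    return Homography(m)


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def warp_tir(
    tir: TIRImage,
    h: Homography,
    target_shape: tuple[int, int],
    mode: str = "nearest",
) -> TIRImage:
    """Resample a TIR raster onto ``target_shape`` through homography ``h``.

    ``h`` maps source (row, col) to target (row, col); each target pixel is
    filled by inverse-mapping into the source.  Targets falling outside the
    source frame come out NaN (missing).  ``mode`` is ``nearest`` (default;
    preserves the sensor's quantised values) or ``bilinear``.
    """
    if mode not in ("nearest", "bilinear"):
        raise ValueError(f"mode must be 'nearest' or 'bilinear', got {mode!r}")
    rows, cols = target_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    targets = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    src_pts = h.inverse().apply(targets)
    coords = src_pts.T.reshape(2, rows, cols)
    order = 0 if mode == "nearest" else 1
    warped = ndimage.map_coordinates(
        tir.values, coords, order=order, mode="constant", cval=np.nan, prefilter=False
    )
    # map_coordinates treats NaN cval only for strictly-outside points; for
    # nearest mode, clamp semantics: mark pixels whose rounded source index
    # is out of bounds as missing explicitly.
    if mode == "nearest":
        r_idx = np.round(coords[0])
        c_idx = np.round(coords[1])
        outside = (
            (r_idx < 0) | (r_idx > tir.shape[0] - 1) |
            (c_idx < 0) | (c_idx > tir.shape[1] - 1)
        )
        warped[outside] = np.nan
    meta = dict(tir.meta)
    meta["warped"] = mode
    return TIRImage(warped, resolution=tir.resolution, meta=meta)
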