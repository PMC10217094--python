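"""Core domain containers shared across the pipeline.

The pipeline couples two imaging modalities of the same pot of plants:
a hyperspectral reflectance cube (hundreds of narrow bands, 400-1000 nm)
and a thermal-infrared temperature raster in deg C.  Everything downstream
— vegetation-index masking, per-band correlation, regression — operates on
these containers plus the point cloud of paired (channel value, temperature)
samples drawn under a plant mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np


class FormatError(ValueError):
    """An on-disk file contradicts its own declaration (shape, band count, ...)."""


class DegenerateImageError(ValueError):
    """An image statistic needed for normalisation is undefined (e.g. constant V)."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a zero-variance sequence."""


@dataclass
class HSICube:
    """A K-band reflectance raster with per-band wavelengths.

    ``values`` is indexed ``[channel, row, col]`` with 0-based channel
    indices; ``wavelengths`` holds the band centre in nm for each channel
    and must be strictly increasing.
    """

    values: np.ndarray            # (K, rows, cols), reflectance
    wavelengths: np.ndarray       # (K,), nm
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("HSICube values must be (channels, rows, cols)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[0]:
            raise ValueError(
                f"wavelength list length {len(self.wavelengths)} does not match "
                f"{self.values.shape[0]} channels"
            )
        if len(self.wavelengths) == 0:
            raise ValueError("HSICube must have at least one channel")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HSICube values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape (rows, cols)."""
        return self.values.shape[1:]

    def wavelength_of(self, channel: int) -> float:
        """Band-centre wavelength in nm of a 0-based channel index."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(
                f"channel {channel} out of range [0, {self.n_channels})"
            )
        return float(self.wavelengths[channel])

    def channel_near(self, target_nm: float) -> int:
        """0-based index of the band nearest ``target_nm``; ties go to the lower index."""
        dist = np.abs(self.wavelengths - float(target_nm))
        return int(np.argmin(dist))  # argmin returns the first (lowest) minimiser

    def band(self, channel: int) -> np.ndarray:
        """The (rows, cols) reflectance image of one channel."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range [0, {self.n_channels})")
        return self.values[channel]

    def select_channels(self, channels: Sequence[int]) -> "HSICube":
        """A new cube restricted to the given (sorted, unique) channel indices."""
        idx = np.asarray(sorted(set(int(c) for c in channels)), dtype=int)
        if idx.size == 0:
            raise ValueError("channel selection must be non-empty")
        if idx[0] < 0 or idx[-1] >= self.n_channels:
            raise IndexError("channel selection out of range")
        return HSICube(self.values[idx], self.wavelengths[idx], dict(self.meta))


@dataclass
class TIRImage:
    """A temperature raster in deg C.

    Missing cells (e.g. pixels that map outside the source frame after
    warping) are NaN; ``missing`` exposes them as a boolean raster.  NaN is
    the explicit missing flag — no numeric sentinel temperature is ever
    used, and all statistics must mask it out.
    """

    values: np.ndarray            # (rows, cols), deg C; NaN = missing
    resolution: float = 0.1       # sensor quantisation step, deg C
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("TIRImage values must be a 2-D raster")
        if not self.resolution > 0:
            raise ValueError("temperature resolution must be > 0")
        if np.any(np.isinf(self.values)):
            raise ValueError("TIRImage values must be finite or NaN (missing)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def quantized(self) -> "TIRImage":
        """Round to the sensor's quantisation grid (NaN preserved)."""
        q = np.round(self.values / self.resolution) * self.resolution
        return TIRImage(q, self.resolution, dict(self.meta))


@dataclass
class PlantMask:
    """Boolean plant raster M_j for key day ``day``, built from NDblue >= thr."""

    member: np.ndarray            # (rows, cols) bool
    thr: float
    day: int = 0

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.ndim != 2:
            raise ValueError("PlantMask must be a 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.member.shape

    @property
    def area(self) -> int:
        """Number of plant pixels (the paper's "Mask, Pix")."""
        return int(self.member.sum())


@dataclass
class IndexMap:
    """Per-pixel NDblue values with the normalisation extremes of V = R550 - R450."""

    values: np.ndarray            # (rows, cols), dimensionless
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.v_max > self.v_min:
            raise DegenerateImageError("v_max must exceed v_min")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("IndexMap values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PointCloud:
    """Paired (channel values, temperature) samples under one mask.

    ``x`` is (n, k) for k selected channels, ``y`` the TIR temperature in
    deg C, with pixel coordinates and the key-day ordinal of every record.
    """

    x: np.ndarray                 # (n, k) channel values
    y: np.ndarray                 # (n,) deg C
    rows: np.ndarray              # (n,) pixel row
    cols: np.ndarray              # (n,) pixel col
    day: int                      # key-day ordinal of these records
    channels: tuple[int, ...]     # 0-based channel indices of x's columns
    n_missing: int = 0            # records dropped for missing TIR

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=np.float64))
        if self.x.shape[0] == 0:
            self.x = self.x.reshape(0, len(self.channels))
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.rows = np.asarray(self.rows, dtype=np.intp).ravel()
        self.cols = np.asarray(self.cols, dtype=np.intp).ravel()
        self.channels = tuple(int(c) for c in self.channels)
        n = self.x.shape[0]
        if not (len(self.y) == len(self.rows) == len(self.cols) == n):
            raise ValueError("PointCloud arrays must share one length")
        if self.x.shape[1] != len(self.channels):
            raise ValueError(
                f"x has {self.x.shape[1]} columns but {len(self.channels)} channels declared"
            )

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def k(self) -> int:
        return len(self.channels)

    def single_channel(self, channel: int | None = None) -> np.ndarray:
        """The x column for ``channel`` (default: the only one)."""
        if channel is None:
            if self.k != 1:
                raise ValueError("cloud holds several channels; name one")
            return self.x[:, 0]
        try:
            j = self.channels.index(int(channel))
        except ValueError:
            raise KeyError(f"channel {channel} not sampled in this cloud") from None
        return self.x[:, j]

    def select_channels(self, channels: Sequence[int]) -> "PointCloud":
        """A new cloud restricted to the given channels (must be sampled here)."""
        chans = [int(c) for c in channels]
        cols = []
        for c in chans:
            try:
                cols.append(self.channels.index(c))
            except ValueError:
                raise KeyError(f"channel {c} not sampled in this cloud") from None
        return replace(self, x=self.x[:, cols], channels=tuple(chans))

    def subset(self, keep: np.ndarray) -> "PointCloud":
        """A new cloud of the records where ``keep`` (bool or index array) selects."""
        keep = np.asarray(keep)
        return replace(
            self,
            x=self.x[keep],
            y=self.y[keep],
            rows=self.rows[keep],
            cols=self.cols[keep],
        )

    def to_frame(self):
        """CSV-ready DataFrame: day, row, col, one column per channel, tir_c."""
        import pandas as pd

        data: dict[str, Any] = {
            "day": np.full(self.n, self.day, dtype=int),
            "row": self.rows,
            "col": self.cols,
        }
        for j, c in enumerate(self.channels):
            data[f"ch{c}"] = self.x[:, j]
        data["tir_c"] = self.y
        return pd.DataFrame(data)


# Column schemas of the CSV study reports, one per report kind.
REPORT_SCHEMAS: dict[str, tuple[str, ...]] = {
    "day_report": (
        "day", "thr", "a", "b", "mask_pix", "cloud_n", "plcc",
        "best_channel", "wavelength_nm", "rmse_c",
        "mask_in_pix", "plcc_in", "rmse_in_c", "rmse_out_c",
    ),
    "train_report": (
        "label", "k", "thr", "a", "b", "train_mask_pix", "test_mask_pix",
        "train_rmse_c", "test_rmse_c", "epochs",
    ),
    "spectrum": ("channel", "wavelength_nm", "r"),
    "extrema": ("channel", "wavelength_nm", "kind"),
}


@dataclass
class ReportTable:
    """Rows of named scalar metrics with a fixed per-kind column schema.

    Every row carries the full parameter tuple that produced it, so any
    line of a study report is traceable back to (day, thr, a, b, ...).
    """

    kind: str
    rows: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in REPORT_SCHEMAS:
            raise ValueError(f"unknown report kind {self.kind!r}")

    @property
    def schema(self) -> tuple[str, ...]:
        return REPORT_SCHEMAS[self.kind]

    def append(self, row: dict[str, Any]) -> None:
        missing = set(self.schema) - set(row)
        if missing:
            raise ValueError(f"report row is missing columns {sorted(missing)}")
        self.rows.append({k: row[k] for k in self.schema})

    def extend(self, rows) -> None:
        for row in rows:
            self.append(row)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=list(self.schema))

    def __len__(self) -> int:
        return len(self.rows)
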