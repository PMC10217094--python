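"""Readers and writers for the pipeline's on-disk formats.

Hyperspectral cubes travel as an ENVI header/raster pair (plain-text
``.hdr`` plus a band-sequential float32 raster, the native layout of
frame-based hyperspectral cameras).  Temperature rasters are single-band
32-bit float TIFFs or plain CSV matrices; plant masks are 8-bit PNGs
(0 = background, 255 = plant) or CSVs of 0/1; study reports are CSV with
a header row.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import FormatError, HSICube, PlantMask, ReportTable, TIRImage

# ENVI numeric data-type codes we accept (code -> numpy dtype).
_ENVI_DTYPES = {2: "<i2", 3: "<i4", 4: "<f4", 5: "<f8", 12: "<u2"}
_ENVI_WRITE_DTYPE = 4  # float32


def _hdr_path(path: str | Path) -> Path:
    p = Path(path)
    if p.suffix.lower() == ".hdr":
        return p
    cand = p.with_suffix(p.suffix + ".hdr") if p.suffix else p.with_suffix(".hdr")
    if cand.exists():
        return cand
    return p.with_suffix(".hdr")


def _parse_envi_header(text: str) -> dict[str, str]:
    """Parse the ``key = value`` lines of an ENVI header; ``{...}`` values may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w\s]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    pos = 0
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def read_hsi(path: str | Path) -> HSICube:
    """Read an ENVI header/raster pair into an :class:`HSICube`.

    ``path`` may point at either member of the pair.  The header's band
    count, raster dimensions and byte layout must agree with the raster
    file's size; the wavelength list is mandatory because every downstream
    step addresses channels by wavelength.
    """
    hdr = _hdr_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr}")
    fields = _parse_envi_header(hdr.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field {exc}") from None
    dtype_code = int(fields.get("data type", _ENVI_WRITE_DTYPE))
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"only band-sequential (bsq) interleave supported, got {interleave!r}")
    offset = int(fields.get("header offset", 0))
    if int(fields.get("byte order", 0)) != 0:
        raise FormatError("only little-endian (byte order = 0) rasters supported")

    if "wavelength" not in fields:
        raise FormatError(
            "ENVI header has no wavelength list; supply a header with per-band "
            "wavelengths (nm) — channels are addressed by wavelength downstream"
        )
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(tok) for tok in wl_text.replace("\n", " ").split(",") if tok.strip()])
    if len(wavelengths) != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    raster = _raster_path(hdr)
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    expected = offset + samples * lines * bands * dtype.itemsize
    actual = raster.stat().st_size
    if actual != expected:
        raise FormatError(
            f"raster {raster.name} holds {actual} bytes but the header implies {expected} "
            f"({bands} bands x {lines} x {samples} x {dtype.itemsize} B)"
        )
    data = np.fromfile(raster, dtype=dtype, offset=offset).reshape(bands, lines, samples)
    meta: dict[str, Any] = {"source": str(raster)}
    if "description" in fields:
        meta["description"] = fields["description"].strip("{} \n")
    return HSICube(data.astype(np.float32), wavelengths, meta)


def _raster_path(hdr: Path) -> Path:
    stem = hdr.with_suffix("")
    for suffix in ("", ".raw", ".img", ".dat", ".bsq"):
        cand = stem.with_suffix(suffix) if suffix else stem
        if cand.exists() and cand != hdr:
            return cand
    raise FileNotFoundError(f"no raster file found next to header {hdr}")


def write_hsi(cube: HSICube, path: str | Path) -> None:
    """Write ``cube`` as an ENVI pair (``<path>.hdr`` + ``<path>.raw``, BSQ float32)."""
    if cube.n_channels == 0:
        raise ValueError("refusing to write an empty cube (K = 0)")
    base = Path(path)
    if base.suffix.lower() in (".hdr", ".raw"):
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    bands, lines, samples = cube.values.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr_text = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_WRITE_DTYPE}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    base.with_suffix(".hdr").write_text(hdr_text)
    cube.values.astype("<f4").tofile(base.with_suffix(".raw"))


def read_tir(path: str | Path, resolution: float = 0.1) -> TIRImage:
    """Read a temperature matrix (deg C) from a single-band TIFF or a CSV matrix."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(p)
        if data.ndim != 2:
            raise FormatError(
                f"TIR TIFF must be single-band, got shape {data.shape}"
            )
        values = np.asarray(data, dtype=np.float64)
    elif p.suffix.lower() in (".csv", ".txt"):
        rows: list[list[float]] = []
        with open(p, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row:
                    continue
                try:
                    rows.append([float(tok) if tok.strip().lower() not in ("", "nan") else np.nan
                                 for tok in row])
                except ValueError as exc:
                    raise FormatError(f"non-numeric entry on CSV row {i}: {exc}") from None
        if not rows:
            raise FormatError("empty TIR CSV")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"ragged TIR CSV: row widths {sorted(widths)}")
        values = np.array(rows, dtype=np.float64)
    else:
        raise FormatError(f"unsupported TIR format {p.suffix!r} (use .tif/.tiff or .csv)")
    return TIRImage(values, resolution=resolution, meta={"source": str(p)})


def write_tir(tir: TIRImage, path: str | Path) -> None:
    """Write a temperature raster as float32 TIFF or CSV, matching :func:`read_tir`."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, tir.values.astype(np.float32))
    elif p.suffix.lower() in (".csv", ".txt"):
        with open(p, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in tir.values:
                writer.writerow([repr(float(v)) for v in row])
    else:
        raise FormatError(f"unsupported TIR format {p.suffix!r}")


def read_mask(path: str | Path, thr: float = float("nan"), day: int = 0) -> PlantMask:
    """Read a plant mask from 8-bit PNG (0/255) or CSV of 0/1."""
    p = Path(path)
    if p.suffix.lower() == ".png":
        img = iio.imread(p)
        if img.ndim == 3:
            img = img[..., 0]
        member = img > 127
    elif p.suffix.lower() == ".csv":
        member = np.loadtxt(p, delimiter=",", dtype=float) > 0.5
        member = np.atleast_2d(member)
    else:
        raise FormatError(f"unsupported mask format {p.suffix!r}")
    return PlantMask(member, thr=thr, day=day)


def write_mask(mask: PlantMask, path: str | Path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.suffix.lower() == ".png":
        iio.imwrite(p, (mask.member.astype(np.uint8) * 255))
    elif p.suffix.lower() == ".csv":
        np.savetxt(p, mask.member.astype(np.uint8), fmt="%d", delimiter=",")
    else:
        raise FormatError(f"unsupported mask format {p.suffix!r}")


def write_report(report: ReportTable, path: str | Path, extra: dict[str, Any] | None = None) -> None:
    """Write a report as CSV with a header row.

    ``extra`` columns (e.g. config hash, seed, stage) are appended to every
    row so each line is traceable to the run that produced it.
    """
    frame = report.to_frame()
    if extra:
        for key, val in extra.items():
            frame[key] = val
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_control_points(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read homography control points: CSV columns src_row, src_col, dst_row, dst_col."""
    data = np.loadtxt(path, delimiter=",", dtype=float, skiprows=_has_header(path))
    data = np.atleast_2d(data)
    if data.shape[1] != 4:
        raise FormatError("control-point CSV needs 4 columns: src_row, src_col, dst_row, dst_col")
    return data[:, :2], data[:, 2:]


def _has_header(path: str | Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(tok) for tok in first.strip().split(",")]
        return 0
    except ValueError:
        return 1
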