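"""Raster data model and I/O.

Grids are plain 2-D numpy arrays with a boolean validity mask (``True`` =
valid land cell, ``False`` = sea / no-data) and minimal georeferencing
metadata.  Row 0 is the northernmost row; indices are 0-based; any lat/lon
reported for a cell refers to its center.

Two on-disk formats are supported: ESRI ASCII grid (the classic
``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` text header) and
single-band float GeoTIFF (written through :mod:`tifffile` with the GDAL
geo-tags ModelPixelScale, ModelTiepoint and GDAL_NODATA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GridMeta",
    "ScoreMap",
    "BinaryMap",
    "CoregistrationError",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "standardize",
    "assert_coregistered",
]

#: sentinel written for invalid cells; outside [0, 1] by construction
DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised when a raster file does not parse as the named format."""


class CoregistrationError(ValueError):
    """Raised when two maps that must share a grid do not."""


@dataclass(frozen=True)
class GridMeta:
    """Shape and georeferencing of a raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both at least 1.
    cell_size
        Cell edge length in degrees per pixel (10 arcmin = 1/6 degree).
    origin
        (lon, lat) of the outer corner of the upper-left cell, i.e. the
        north-west corner of the grid.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0 / 6.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        lon0, lat0 = self.origin
        return (
            lon0 + (col + 0.5) * self.cell_size,
            lat0 - (row + 0.5) * self.cell_size,
        )


@dataclass
class ScoreMap:
    """A continuous raster of model scores with a validity mask."""

    meta: GridMeta
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.meta.shape or self.mask.shape != self.meta.shape:
            raise ValueError(
                f"values/mask shape {self.values.shape}/{self.mask.shape} "
                f"does not match meta shape {self.meta.shape}"
            )

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of the values at valid cells (row-major order)."""
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray) -> "ScoreMap":
        return ScoreMap(self.meta, np.asarray(values, dtype=float), self.mask.copy())


@dataclass
class BinaryMap:
    """A presence/absence raster: valid cells are exactly 0 or 1."""

    meta: GridMeta
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.meta.shape or self.mask.shape != self.meta.shape:
            raise ValueError("values/mask shape does not match meta shape")
        vv = self.values[self.mask]
        if vv.size and not np.isin(vv, (0, 1)).all():
            raise ValueError("valid cells of a BinaryMap must be exactly 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def as_score_map(self) -> ScoreMap:
        return ScoreMap(self.meta, self.values.astype(float), self.mask.copy())


# ---------------------------------------------------------------------------
# co-registration and standardisation
# ---------------------------------------------------------------------------

def assert_coregistered(a: ScoreMap | BinaryMap, b: ScoreMap | BinaryMap) -> None:
    """Require two maps to live on the same grid with identical masks.

    Masks must be *identical*: the intersection is never taken silently,
    so a mask discrepancy surfaces as an error instead of quietly shrinking
    the comparison domain.
    """
    if a.meta != b.meta:
        for f in ("n_rows", "n_cols", "cell_size", "origin"):
            if getattr(a.meta, f) != getattr(b.meta, f):
                raise CoregistrationError(
                    f"grid metadata differs in {f!r}: "
                    f"{getattr(a.meta, f)} != {getattr(b.meta, f)}"
                )
    if not np.array_equal(a.mask, b.mask):
        n = int((a.mask != b.mask).sum())
        raise CoregistrationError(f"masks differ at {n} cell(s)")


def standardize(m: ScoreMap) -> ScoreMap:
    """Min-max rescale the valid cells to span [0, 1].

    ``v' = (v - min) / (max - min)`` over valid cells only; invalid cells
    are left untouched.  A constant map (max == min) maps every valid cell
    to 0: a flat score carries no discrimination, and 0 keeps downstream
    dichotomisation conservative.
    """
    vv = m.valid_values()
    if vv.size == 0:
        raise ValueError("standardize requires at least one valid cell")
    lo, hi = float(vv.min()), float(vv.max())
    out = m.values.astype(float).copy()
    if hi > lo:
        out[m.mask] = (vv - lo) / (hi - lo)
    else:
        out[m.mask] = 0.0
    return m.copy_with(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: Path, nodata: float | None) -> ScoreMap:
    with open(path) as fh:
        tokens: dict[str, float] = {}
        lines = fh.readlines()
    pos = 0
    file_nodata = None
    for pos, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"bad header value in {path}: {line!r}") from exc
            if key == "nodata_value":
                file_nodata = val
            else:
                tokens[key] = val
        else:
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in tokens]
    if missing:
        raise GridFormatError(f"{path}: missing header field(s) {missing}")
    n_rows, n_cols = int(tokens["nrows"]), int(tokens["ncols"])
    cell = tokens["cellsize"]
    try:
        data = np.loadtxt(lines[pos:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise GridFormatError(f"{path}: malformed data block: {exc}") from exc
    if data.shape != (n_rows, n_cols):
        data = data.reshape(-1)
        if data.size != n_rows * n_cols:
            raise GridFormatError(
                f"{path}: data block has {data.size} values, "
                f"expected {n_rows * n_cols}"
            )
        data = data.reshape(n_rows, n_cols)
    nd = nodata if nodata is not None else file_nodata
    if nd is None:
        nd = DEFAULT_NODATA
    mask = ~(np.isclose(data, nd) | np.isnan(data))
    # ASCII grids are corner-registered at the lower-left; convert to our
    # upper-left origin convention.
    origin = (tokens["xllcorner"], tokens["yllcorner"] + n_rows * cell)
    meta = GridMeta(n_rows=n_rows, n_cols=n_cols, cell_size=cell, origin=origin)
    return ScoreMap(meta, data, mask)


def _write_ascii_grid(m: ScoreMap | BinaryMap, path: Path, nodata: float) -> None:
    lon0, lat0 = m.meta.origin
    yll = lat0 - m.meta.n_rows * m.meta.cell_size
    vals = np.where(m.mask, m.values.astype(float), nodata)
    header = (
        f"ncols {m.meta.n_cols}\n"
        f"nrows {m.meta.n_rows}\n"
        f"xllcorner {float(lon0):.17g}\n"
        f"yllcorner {float(yll):.17g}\n"
        f"cellsize {float(m.meta.cell_size):.17g}\n"
        f"NODATA_value {float(nodata):.17g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path, nodata: float | None) -> ScoreMap:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(float)
            tags = {t.code: t.value for t in page.tags.values()}
    except (tifffile.TiffFileError, OSError) as exc:
        raise GridFormatError(f"{path}: not a readable TIFF: {exc}") from exc
    if data.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster")
    cell = 1.0
    origin = (0.0, 0.0)
    if _TAG_MODEL_PIXEL_SCALE in tags:
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise GridFormatError(f"{path}: anisotropic pixels not supported")
        cell = float(sx)
    if _TAG_MODEL_TIEPOINT in tags:
        tp = tags[_TAG_MODEL_TIEPOINT]
        # tie the raster point (tp[0], tp[1]) to model (tp[3], tp[4])
        origin = (float(tp[3]) - tp[0] * cell, float(tp[4]) + tp[1] * cell)
    nd = nodata
    if nd is None and _TAG_GDAL_NODATA in tags:
        nd = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00"))
    if nd is None:
        nd = DEFAULT_NODATA
    mask = ~(np.isclose(data, nd) | np.isnan(data))
    meta = GridMeta(
        n_rows=data.shape[0], n_cols=data.shape[1], cell_size=cell, origin=origin
    )
    return ScoreMap(meta, data, mask)


def _write_geotiff(m: ScoreMap | BinaryMap, path: Path, nodata: float) -> None:
    import tifffile

    lon0, lat0 = m.meta.origin
    cell = m.meta.cell_size
    vals = np.where(m.mask, m.values.astype(float), nodata).astype(np.float64)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cell, cell, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, lon0, lat0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_grid(
    path: str | Path,
    format: str | None = None,
    nodata: float | None = None,
    binary: bool = False,
) -> ScoreMap | BinaryMap:
    """Read a raster from ``path``.

    Parameters
    ----------
    format
        ``"geotiff"`` or ``"ascii_grid"``; inferred from the file suffix
        (.tif/.tiff vs .asc/.txt) when omitted.
    nodata
        Overrides the no-data value declared in the file.
    binary
        Return a :class:`BinaryMap` (valid cells must round-trip {0, 1}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if format == "ascii_grid":
        sm = _read_ascii_grid(path, nodata)
    elif format == "geotiff":
        sm = _read_geotiff(path, nodata)
    else:
        raise ValueError(f"unknown raster format {format!r}")
    if binary:
        return BinaryMap(sm.meta, np.rint(sm.values).astype(np.int8), sm.mask)
    return sm


def write_grid(
    m: ScoreMap | BinaryMap,
    path: str | Path,
    format: str | None = None,
    nodata: float = DEFAULT_NODATA,
) -> None:
    """Write a raster; the result re-reads with equal meta, values and mask."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if format == "ascii_grid":
        _write_ascii_grid(m, path, nodata)
    elif format == "geotiff":
        _write_geotiff(m, path, nodata)
    else:
        raise ValueError(f"unknown raster format {format!r}")
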