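"""Raster containers and plain-text grid I/O.

Grids are stored on a regular planar lattice in an equal-area local
projection: row 0 is the northernmost row, coordinates refer to cell
centers, and ``cell_size`` is the linear cell edge in metres.  On disk each
band is an ESRI ASCII grid (``.asc``), a plain-text format readable by GDAL
and QGIS.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NODATA = -9999.0


class GridError(ValueError):
    """Raised for malformed or inconsistent raster inputs."""


@dataclass
class ClimateGrid:
    """Multiband climate raster: one band per climate variable.

    ``data`` has shape (n_bands, rows, cols); cells where ``mask`` is False
    are outside the modelled range and are excluded from every downstream
    statistic.  All bands share one geometry and one mask.
    """

    data: np.ndarray
    band_names: list[str]
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    mask: np.ndarray | None = None
    crs: str = "local-equal-area"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GridError("ClimateGrid data must be 3-D (bands, rows, cols)")
        if len(self.band_names) != self.data.shape[0]:
            raise GridError(
                f"{len(self.band_names)} band names for {self.data.shape[0]} bands"
            )
        if len(set(self.band_names)) != len(self.band_names):
            raise GridError("duplicate band names")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise GridError("mask shape does not match band shape")
        if not np.isfinite(self.data[:, self.mask]).all():
            raise GridError("non-finite values inside the valid mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def band(self, name: str) -> np.ndarray:
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise GridError(f"band {name!r} absent from grid") from None
        return self.data[i]

    def valid_table(self) -> np.ndarray:
        """Masked-in cells as an (n_valid, n_bands) array, row-major cell order."""
        return self.data[:, self.mask].T.copy()

    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


@dataclass
class ZoneMap:
    """Categorical raster of seed/breeding zone labels.

    Label 0 marks cells outside the species range; every in-range cell
    carries exactly one positive integer zone id.
    """

    labels: np.ndarray
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "local-equal-area"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GridError("ZoneMap labels must be a 2-D raster")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise GridError("zone labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if (self.labels < 0).any():
            raise GridError("zone labels must be >= 0 (0 = outside range)")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def zone_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(z) for z in ids if z > 0]

    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def same_geometry(self, other: "ZoneMap") -> bool:
        return (
            self.labels.shape == other.labels.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
            and self.crs == other.crs
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_asc(path: str | Path, values: np.ndarray, cell_size: float,
              x_origin: float = 0.0, y_origin: float = 0.0,
              mask: np.ndarray | None = None, fmt: str = "%.6g") -> Path:
    """Write one band as an ESRI ASCII grid; masked cells become NODATA."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, bool)] = NODATA
    # .asc origin is the lower-left corner; our y_origin is the top-left.
    yll = y_origin - rows * cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\n")
        fh.write(f"xllcorner {x_origin:.6f}\nyllcorner {yll:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\nNODATA_value {NODATA:g}\n")
        for r in range(rows):
            fh.write(" ".join(fmt % v for v in out[r]) + "\n")
    return path


def read_asc(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid.

    Returns (values, mask, cell_size, x_origin, y_origin_top).
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows_txt: list[str] = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if len(toks) == 2 and re.match(r"(?i)^[a-z_]+$", toks[0]):
                header[toks[0].lower()] = float(toks[1])
            else:
                rows_txt.append(line)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridError(f"{path.name}: missing ASCII-grid header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", NODATA)
    try:
        values = np.loadtxt(rows_txt, dtype=float, ndmin=2)
    except ValueError as exc:
        raise GridError(f"{path.name}: malformed data rows ({exc})") from exc
    if values.shape != (nrows, ncols):
        raise GridError(
            f"{path.name}: data shape {values.shape} != header ({nrows}, {ncols})"
        )
    mask = values != nodata
    cell = header["cellsize"]
    y_top = header["yllcorner"] + nrows * cell
    return values, mask, cell, header["xllcorner"], y_top


def write_climate_grid(grid: ClimateGrid, directory: str | Path) -> list[Path]:
    """Write each band of a ClimateGrid as ``<band>.asc`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, band in zip(grid.band_names, grid.data):
        paths.append(
            write_asc(directory / f"{name}.asc", band, grid.cell_size,
                      grid.x_origin, grid.y_origin, grid.mask)
        )
    return paths


def read_climate_grid(paths: Iterable[str | Path] | str | Path,
                      band_names: Sequence[str] | None = None) -> ClimateGrid:
    """Assemble a ClimateGrid from per-band .asc files.

    *paths* is either a directory containing ``<band>.asc`` files or an
    explicit iterable of files (band name = file stem).  All bands must be
    co-registered; their NODATA cells must agree, forming the shared mask.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        files = sorted(Path(paths).glob("*.asc"))
    else:
        files = [Path(p) for p in paths]  # type: ignore[union-attr]
    if not files:
        raise GridError("no .asc band files found")
    if band_names is not None:
        by_stem = {f.stem: f for f in files}
        missing = [b for b in band_names if b not in by_stem]
        if missing:
            raise GridError(f"band files absent for: {', '.join(missing)}")
        files = [by_stem[b] for b in band_names]
    names, bands, masks = [], [], []
    geom = None
    for f in files:
        values, mask, cell, x0, y0 = read_asc(f)
        this_geom = (values.shape, round(cell, 9), round(x0, 6), round(y0, 6))
        if geom is None:
            geom = this_geom
        elif this_geom != geom:
            raise GridError(
                f"band {f.stem!r} geometry {this_geom} differs from {geom}"
            )
        names.append(f.stem)
        bands.append(values)
        masks.append(mask)
    mask = masks[0]
    for nm, m in zip(names, masks):
        if not np.array_equal(m, mask):
            raise GridError(f"band {nm!r} NODATA mask differs across bands")
    _, cell9, x0, y0 = geom  # type: ignore[misc]
    return ClimateGrid(np.stack(bands), names, cell9, x0, y0, mask)


def write_zone_map(zmap: ZoneMap, path: str | Path) -> Path:
    """Persist a ZoneMap as a single-band categorical ASCII grid."""
    return write_asc(Path(path), zmap.labels.astype(float), zmap.cell_size,
                     zmap.x_origin, zmap.y_origin, zmap.mask, fmt="%d")


def read_zone_map(path: str | Path, provenance: str = "") -> ZoneMap:
    values, mask, cell, x0, y0 = read_asc(path)
    labels = np.where(mask, values, 0.0)
    if not np.all(labels == np.round(labels)):
        raise GridError(f"{Path(path).name}: zone labels are not integral")
    return ZoneMap(labels.astype(np.int64), cell, x0, y0, provenance=provenance)
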