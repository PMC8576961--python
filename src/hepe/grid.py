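"""Raster data model and I/O: analysis grids, population rasters, station series.

Grid convention: row 0 is the northern edge (north-up), ``origin_x``/``origin_y``
is the outer (north-west) corner of cell (0, 0), and all coordinate math uses
cell centers. Rasters travel on disk as ESRI ASCII grids (``.asc``) — a plain
text, georeferenced single-band format — with a ``.prj`` sidecar holding the
CRS label. Tables are CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .crs import LocalProjection, check_projected

logger = logging.getLogger(__name__)

NODATA = -9999.0

STATION_CSV_COLUMNS = ("station_id", "lon", "lat", "hour", "pm25")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular north-up analysis raster in projected meters.

    ``origin_x``/``origin_y`` locate the outer corner of cell (0, 0); rows
    increase southward, columns eastward. The cell-center of cell (r, c) is
    ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "LOCAL[m]"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        check_projected(self.crs_label)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def x_min(self) -> float:
        return self.origin_x

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin_y

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_size

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinate arrays, each of shape (n_rows, n_cols)."""
        X, Y = np.meshgrid(self.x_centers(), self.y_centers())
        return X, Y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing point (x, y)."""
        c = int(np.floor((x - self.origin_x) / self.cell_size))
        r = int(np.floor((self.origin_y - y) / self.cell_size))
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        return r, c

    def same_extent(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            abs(self.x_min - other.x_min) < tol
            and abs(self.x_max - other.x_max) < tol
            and abs(self.y_min - other.y_min) < tol
            and abs(self.y_max - other.y_max) < tol
        )


def _check_field(values: np.ndarray, grid: GridSpec, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid {grid.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(values < 0):
        raise ValueError(f"{name} contains negative values")
    return values


@dataclass
class PopulationRaster:
    """Non-negative density/count surface on a grid.

    ``source_tag`` distinguishes the hourly social-media-derived ambulatory
    population (``sm``) from the modelled older-adult population (``psd``);
    ``hour`` is an integer 0-23 or ``"static"`` for the diurnally constant
    elderly raster.
    """

    grid: GridSpec
    values: np.ndarray
    source_tag: str
    hour: int | str = "static"

    def __post_init__(self) -> None:
        if self.source_tag not in ("sm", "psd"):
            raise ValueError(f"source_tag must be 'sm' or 'psd', got {self.source_tag!r}")
        self.values = _check_field(self.values, self.grid, "population raster")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class StationSeries:
    """Hourly PM2.5 record of one monitoring station; NaN marks missing hours."""

    station_id: str
    x: float
    y: float
    lon: float
    lat: float
    hours: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=int)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.hours.shape != self.conc.shape:
            raise ValueError("hours and conc must have the same length")
        if np.any(np.diff(self.hours) <= 0):
            raise ValueError("hours must be strictly increasing")
        present = np.isfinite(self.conc)
        if np.any(self.conc[present] < 0):
            raise ValueError("present concentrations must be >= 0")

    def value_at(self, hour: int) -> float:
        """Concentration at ``hour``; NaN when the hour is absent or missing."""
        idx = np.nonzero(self.hours == hour)[0]
        return float(self.conc[idx[0]]) if idx.size else float("nan")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.conc).sum())


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid + .prj sidecar)
# ---------------------------------------------------------------------------


def write_raster(
    values: np.ndarray,
    grid: GridSpec,
    path: str | Path,
    nodata: float = NODATA,
) -> None:
    """Write a field as a georeferenced ESRI ASCII grid; NaN cells become nodata."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_min:.17g}\n"
        f"yllcorner {grid.y_min:.17g}\n"
        f"cellsize {grid.cell_size:.17g}\n"
        f"NODATA_value {nodata:.17g}\n"
    )
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in out)
    path.write_text(header + body + "\n")
    path.with_suffix(".prj").write_text(grid.crs_label + "\n")


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid.

    Returns ``(values, grid, nodata_mask)`` with nodata cells as NaN in
    ``values`` and True in ``nodata_mask``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: malformed ASCII grid header (missing {key})")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: body shape {values.shape} != header ({n_rows}, {n_cols})")
    prj = path.with_suffix(".prj")
    crs_label = prj.read_text().strip() if prj.exists() else "LOCAL[m]"
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        crs_label=crs_label,
    )
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    return values, grid, mask


def read_population_raster(path: str | Path, source_tag: str, hour: int | str) -> PopulationRaster:
    """Load a population raster; negative/nodata cells are zeroed (logged)."""
    values, grid, mask = read_raster(path)
    n_bad = int(mask.sum() + (values < 0).sum())
    if n_bad:
        logger.warning("%s: %d nodata/negative cells set to 0", path, n_bad)
    values = np.where(mask | (values < 0), 0.0, values)
    return PopulationRaster(grid=grid, values=values, source_tag=source_tag, hour=hour)


# ---------------------------------------------------------------------------
# station CSV
# ---------------------------------------------------------------------------


def read_station_csv(path: str | Path, projection: LocalProjection) -> list[StationSeries]:
    """Read a station CSV (station_id, lon, lat, hour, pm25) into series.

    Coordinates are projected into the analysis CRS via ``projection``.
    Unparseable or negative pm25 entries become missing (NaN), left for QC.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in STATION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no station rows")
    conc = pd.to_numeric(df["pm25"], errors="coerce")
    conc = conc.where(conc >= 0)  # negative (incl. -9999 sentinels) -> missing
    df = df.assign(pm25=conc)
    series = []
    for sid, g in df.groupby("station_id", sort=True):
        g = g.sort_values("hour")
        lon, lat = float(g["lon"].iloc[0]), float(g["lat"].iloc[0])
        x, y = projection.forward(lon, lat)
        series.append(
            StationSeries(
                station_id=str(sid),
                x=float(x),
                y=float(y),
                lon=lon,
                lat=lat,
                hours=g["hour"].to_numpy(dtype=int),
                conc=g["pm25"].to_numpy(dtype=float),
            )
        )
    return series


def write_station_csv(series: Sequence[StationSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for h, c in zip(s.hours, s.conc):
            rows.append(
                {
                    "station_id": s.station_id,
                    "lon": s.lon,
                    "lat": s.lat,
                    "hour": int(h),
                    "pm25": c,
                }
            )
    pd.DataFrame(rows, columns=list(STATION_CSV_COLUMNS)).to_csv(
        path, index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# resampling between nested grids
# ---------------------------------------------------------------------------


def resample_to_grid(raster: PopulationRaster, target: GridSpec) -> PopulationRaster:
    """Mass-preserving resampling between nested grids of integer cell-size ratio.

    Coarse -> fine disaggregates each coarse count equally among its nested
    fine cells; fine -> coarse sums. Total population is conserved exactly up
    to floating point.
    """
    src = raster.grid
    if not src.same_extent(target):
        raise ValueError("source and target grids must cover the same extent")
    ratio = src.cell_size / target.cell_size
    if ratio >= 1:  # disaggregate
        f = int(round(ratio))
        if abs(ratio - f) > 1e-9 or src.n_rows * f != target.n_rows or src.n_cols * f != target.n_cols:
            raise ValueError("grids are not nested with an integer cell-size ratio")
        values = np.kron(raster.values, np.ones((f, f))) / (f * f)
    else:  # aggregate
        f = int(round(1.0 / ratio))
        if abs(1.0 / ratio - f) > 1e-9 or target.n_rows * f != src.n_rows or target.n_cols * f != src.n_cols:
            raise ValueError("grids are not nested with an integer cell-size ratio")
        values = raster.values.reshape(target.n_rows, f, target.n_cols, f).sum(axis=(1, 3))
    return PopulationRaster(grid=target, values=values, source_tag=raster.source_tag, hour=raster.hour)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(
    records: Iterable[dict] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records to CSV; an empty record list yields a header-only file."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        df = pd.DataFrame(records, columns=columns if (columns and not records) else None)
        if columns is not None:
            df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
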