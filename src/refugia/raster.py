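"""Lightweight georeferenced raster container and text-format I/O.

A :class:`RasterGrid` is a single-band 2-D field on a regular
latitude/longitude grid: row 0 is the northern edge, columns run west to
east, and missing cells are NaN.  It is the carrier for monthly climate
normals, derived bioclimatic variables, probability-of-presence surfaces
and habitat-stability surfaces throughout the package.

Grids are read and written as ESRI ASCII grid (``.asc``) — a plain-text
format understood by GDAL, QGIS and ArcGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

__all__ = ["RasterGrid", "GeometryError", "read_ascii_grid", "write_ascii_grid"]


class GeometryError(ValueError):
    """Raised when raster geometries that must match do not."""


@dataclass(frozen=True)
class RasterGrid:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    data
        2-D float array; NaN marks nodata cells.
    x0, y0
        Longitude of the west edge and latitude of the north edge, in
        degrees.
    cell_size
        Cell width/height in degrees (square cells).
    name
        Variable name carried in exports.
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("raster data must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "data", arr)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.data)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) edges in degrees."""
        nrow, ncol = self.shape
        return (
            self.x0,
            self.y0 - nrow * self.cell_size,
            self.x0 + ncol * self.cell_size,
            self.y0,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lons, lats) of cell centres, 1-D along each axis."""
        nrow, ncol = self.shape
        lons = self.x0 + (np.arange(ncol) + 0.5) * self.cell_size
        lats = self.y0 - (np.arange(nrow) + 0.5) * self.cell_size
        return lons, lats

    def same_geometry(self, other: "RasterGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= atol
            and abs(self.y0 - other.y0) <= atol
            and abs(self.cell_size - other.cell_size) <= atol
        )

    def require_same_geometry(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"raster geometries differ: {self.shape}@({self.x0},{self.y0},"
                f"{self.cell_size}) vs {other.shape}@({other.x0},{other.y0},"
                f"{other.cell_size})"
            )

    # ------------------------------------------------------------------
    def index_of(self, lon: np.ndarray, lat: np.ndarray):
        """Row/col of the cells containing the given coordinates.

        Returns ``(rows, cols, inside)`` where *inside* flags points within
        the grid bounds; rows/cols of outside points are clipped and must
        not be used.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - lat) / self.cell_size).astype(int)
        nrow, ncol = self.shape
        inside = (col >= 0) & (col < ncol) & (row >= 0) & (row < nrow)
        return np.clip(row, 0, nrow - 1), np.clip(col, 0, ncol - 1), inside

    def with_data(self, data: np.ndarray, name: str | None = None) -> "RasterGrid":
        """New grid with the same geometry and different values."""
        return RasterGrid(
            data, self.x0, self.y0, self.cell_size,
            self.name if name is None else name,
        )

    def to_dataarray(self) -> xr.DataArray:
        lons, lats = self.cell_centers()
        return xr.DataArray(
            self.data,
            coords={"lat": lats, "lon": lons},
            dims=("lat", "lon"),
            name=self.name or None,
        )


# ----------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    nrow, ncol = grid.shape
    data = np.where(np.isnan(grid.data), _NODATA, grid.data)
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0 - nrow * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path, name: str = "") -> RasterGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrow = int(header["nrows"])
    ncol = int(header["ncols"])
    data = np.asarray(data, dtype=float).reshape(nrow, ncol)
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    cell = header["cellsize"]
    return RasterGrid(
        data,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrow * cell,
        cell_size=cell,
        name=name or Path(path).stem,
    )
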