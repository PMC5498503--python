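"""Containers for monthly climate normals, at a point and on a grid.

Monthly normals are the 36 inputs of the whole pipeline: twelve monthly
average minimum temperatures, twelve monthly average maximum temperatures
(°C) and twelve monthly precipitation totals (mm).  A 365-day non-leap
calendar is used throughout, with fixed month lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GeometryError, RasterGrid

__all__ = ["MONTH_LENGTHS", "MonthlyNormals", "ClimateNormalGrid"]

#: Days per month, non-leap calendar (365-day year).
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

_MONTH_NAMES = [
    "jan", "feb", "mar", "apr", "may", "jun",
    "jul", "aug", "sep", "oct", "nov", "dec",
]


def _check12(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] != 12:
        raise ValueError(f"{label} must have 12 monthly values, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class MonthlyNormals:
    """Monthly climate normals at a single location.

    ``tmin``/``tmax`` in °C, ``precip`` in mm; each of length 12
    (January first).
    """

    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        tmin = _check12(self.tmin, "tmin")
        tmax = _check12(self.tmax, "tmax")
        precip = _check12(self.precip, "precip")
        if np.any(tmax < tmin):
            raise ValueError("tmax must be >= tmin in every month")
        if np.any(precip < 0):
            raise ValueError("precipitation must be non-negative")
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmax", tmax)
        object.__setattr__(self, "precip", precip)

    @property
    def tmean(self) -> np.ndarray:
        """Monthly mean temperature, (tmin + tmax) / 2."""
        return (self.tmin + self.tmax) / 2.0


@dataclass(frozen=True)
class ClimateNormalGrid:
    """Monthly climate normals on a regular grid: three (12, nrow, ncol)
    stacks sharing one geometry.

    Nodata is NaN; a NaN in any month of any variable makes the cell
    nodata for every derived quantity.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        tmin = np.asarray(self.tmin, dtype=float)
        tmax = np.asarray(self.tmax, dtype=float)
        precip = np.asarray(self.precip, dtype=float)
        for name, arr in (("tmin", tmin), ("tmax", tmax), ("precip", precip)):
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise ValueError(f"{name} must have shape (12, nrow, ncol)")
        if not (tmin.shape == tmax.shape == precip.shape):
            raise GeometryError("tmin, tmax and precip stacks must share geometry")
        with np.errstate(invalid="ignore"):
            if np.any(tmax < tmin):
                raise ValueError("tmax must be >= tmin at every cell and month")
            if np.any(precip < 0):
                raise ValueError("precipitation must be non-negative")
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmax", tmax)
        object.__setattr__(self, "precip", precip)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin.shape[1:]

    @property
    def nodata_mask(self) -> np.ndarray:
        """True where any of the 36 layers is nodata."""
        return (
            np.isnan(self.tmin).any(axis=0)
            | np.isnan(self.tmax).any(axis=0)
            | np.isnan(self.precip).any(axis=0)
        )

    def layer(self, variable: str, month: int) -> RasterGrid:
        """One monthly layer as a :class:`RasterGrid`.

        ``variable`` is 'tmin', 'tmax' or 'precip'; ``month`` is 1-based.
        """
        if variable not in ("tmin", "tmax", "precip"):
            raise KeyError(variable)
        stack = getattr(self, variable)
        return RasterGrid(
            stack[month - 1], self.x0, self.y0, self.cell_size,
            name=f"{variable}_{_MONTH_NAMES[month - 1]}",
        )

    def layers(self) -> list[RasterGrid]:
        """All 36 layers, ordered tmin 1-12, tmax 1-12, precip 1-12."""
        return [
            self.layer(var, m)
            for var in ("tmin", "tmax", "precip")
            for m in range(1, 13)
        ]

    def at(self, row: int, col: int) -> MonthlyNormals:
        """The monthly normals of one cell."""
        return MonthlyNormals(
            self.tmin[:, row, col],
            self.tmax[:, row, col],
            self.precip[:, row, col],
        )

    def geometry_grid(self) -> RasterGrid:
        """An empty grid carrying only this geometry (for checks/templates)."""
        return RasterGrid(
            np.zeros(self.shape), self.x0, self.y0, self.cell_size
        )
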