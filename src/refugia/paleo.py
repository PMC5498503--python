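"""Delta-method palaeoclimate overlay.

Coarse climate-model anomalies are combined with a fine-resolution
baseline by the standard anomaly ("delta") method: monthly temperature
anomalies are additive (°C, applied to both tmin and tmax), monthly
precipitation anomalies are multiplicative factors (unitless, > 0), so
downscaled precipitation can never go negative.  Anomaly layers are
regridded to the baseline geometry by bilinear interpolation of the
coarse cell-centre values.

An additive precipitation mode (clamped at zero) is available for
sensitivity runs via ``apply_delta(..., precip_mode="additive")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .climate import ClimateNormalGrid
from .raster import GeometryError, RasterGrid

__all__ = ["AnomalyGrid", "regrid_anomaly", "apply_delta"]


@dataclass(frozen=True)
class AnomalyGrid:
    """Monthly anomalies for one palaeo period on a (usually coarse) grid.

    ``dt`` holds twelve additive temperature anomalies (°C) and
    ``pfactor`` twelve multiplicative precipitation factors, each of
    shape (12, nrow, ncol).
    """

    period: str
    dt: np.ndarray
    pfactor: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        dt = np.asarray(self.dt, dtype=float)
        pf = np.asarray(self.pfactor, dtype=float)
        if dt.ndim != 3 or dt.shape[0] != 12:
            raise ValueError("dt must have shape (12, nrow, ncol)")
        if pf.shape != dt.shape:
            raise GeometryError("dt and pfactor must share geometry")
        with np.errstate(invalid="ignore"):
            if np.any(pf <= 0):
                raise ValueError("precipitation factors must be positive")
        object.__setattr__(self, "dt", dt)
        object.__setattr__(self, "pfactor", pf)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dt.shape[1:]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        nrow, ncol = self.shape
        return (
            self.x0,
            self.y0 - nrow * self.cell_size,
            self.x0 + ncol * self.cell_size,
            self.y0,
        )

    def geometry_grid(self) -> RasterGrid:
        return RasterGrid(np.zeros(self.shape), self.x0, self.y0, self.cell_size)


def _bilinear_stack(stack: np.ndarray, src: AnomalyGrid,
                    lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Bilinearly interpolate each of the 12 layers to (lats × lons)."""
    nrow, ncol = src.shape
    src_lons = src.x0 + (np.arange(ncol) + 0.5) * src.cell_size
    src_lats = src.y0 - (np.arange(nrow) + 0.5) * src.cell_size
    # flip latitude to ascending order for the interpolator
    pts_lat, pts_lon = np.meshgrid(lats, lons, indexing="ij")
    query = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])
    out = np.empty((12, lats.size, lons.size))
    for m in range(12):
        f = RegularGridInterpolator(
            (src_lats[::-1], src_lons), stack[m, ::-1, :],
            method="linear", bounds_error=False, fill_value=None,
        )
        out[m] = f(query).reshape(lats.size, lons.size)
    return out


def regrid_anomaly(anomaly: AnomalyGrid, target: RasterGrid) -> AnomalyGrid:
    """Regrid an anomaly to the target geometry by bilinear interpolation.

    The target extent must fall inside the anomaly's extent.  Values at
    target centres beyond the outermost source cell centres are obtained
    by linear extension, so constant and planar fields are reproduced
    exactly everywhere.
    """
    tb = target.bounds
    ab = anomaly.bounds
    tol = 1e-9
    if not (ab[0] <= tb[0] + tol and ab[1] <= tb[1] + tol
            and tb[2] <= ab[2] + tol and tb[3] <= ab[3] + tol):
        raise GeometryError(
            f"target extent {tb} outside anomaly coverage {ab}"
        )
    if (anomaly.shape == target.shape
            and anomaly.geometry_grid().same_geometry(target)):
        return AnomalyGrid(
            anomaly.period, anomaly.dt.copy(), anomaly.pfactor.copy(),
            target.x0, target.y0, target.cell_size,
        )
    lons, lats = target.cell_centers()
    dt = _bilinear_stack(anomaly.dt, anomaly, lons, lats)
    pf = _bilinear_stack(anomaly.pfactor, anomaly, lons, lats)
    return AnomalyGrid(
        anomaly.period, dt, pf, target.x0, target.y0, target.cell_size
    )


def apply_delta(baseline: ClimateNormalGrid, anomaly: AnomalyGrid,
                precip_mode: str = "multiplicative") -> ClimateNormalGrid:
    """Overlay anomalies on the baseline normals (delta method).

    tmin' = tmin + ΔT, tmax' = tmax + ΔT, precip' = precip × factor
    (or precip + (factor − 1), clamped at 0, in additive mode).  The
    anomaly must already be on the baseline geometry — use
    :func:`regrid_anomaly` first.  Nodata propagates from the baseline.
    """
    if anomaly.shape != baseline.shape or not anomaly.geometry_grid(
            ).same_geometry(baseline.geometry_grid()):
        raise GeometryError(
            "anomaly must be on the baseline geometry; regrid it first"
        )
    tmin = baseline.tmin + anomaly.dt
    tmax = baseline.tmax + anomaly.dt
    if precip_mode == "multiplicative":
        precip = baseline.precip * anomaly.pfactor
    elif precip_mode == "additive":
        precip = np.maximum(baseline.precip + (anomaly.pfactor - 1.0), 0.0)
    else:
        raise ValueError("precip_mode must be 'multiplicative' or 'additive'")
    return ClimateNormalGrid(
        tmin, tmax, precip, baseline.x0, baseline.y0, baseline.cell_size
    )
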