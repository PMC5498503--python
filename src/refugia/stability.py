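"""Glacial-refugium habitat-stability surfaces.

The stability of a location through the glacial cycle is estimated as
the cellwise product of the probability of presence under the modern
reference climate and under the Last Glacial Maximum: a cell scores high
only if habitat is likely in both states, so the product bounds the
chance that the location stayed habitable throughout.  The surface can
be classified into low / moderate / high stability with configurable
thresholds, and summarised by class area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["stability_map", "classify_stability", "StabilityClassification"]

#: Category codes in the classified layer.
CATEGORIES = {0: "low", 1: "moderate", 2: "high"}


def stability_map(p_now: RasterGrid, p_lgm: RasterGrid) -> RasterGrid:
    """Cellwise product of present-day and LGM probability surfaces.

    Nodata in either input propagates.  Values must be probabilities;
    the result is again in [0, 1] and never exceeds either input.
    """
    p_now.require_same_geometry(p_lgm)
    for grid in (p_now, p_lgm):
        vals = grid.data[~np.isnan(grid.data)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("probability surfaces must lie in [0, 1]")
    return p_now.with_data(p_now.data * p_lgm.data, name="stability")


@dataclass
class StabilityClassification:
    """Classified stability layer plus an area summary."""

    categories: RasterGrid          # 0 = low, 1 = moderate, 2 = high, NaN nodata
    summary: pd.DataFrame           # class, n_cells, area (cell_size² units)
    thresholds: tuple[float, float]


def classify_stability(surface: RasterGrid,
                       thresholds: tuple[float, float] = (0.25, 0.5)
                       ) -> StabilityClassification:
    """Classify a stability surface into low / moderate / high.

    ``thresholds = (t_mod, t_high)`` with 0 < t_mod < t_high < 1:
    low < t_mod ≤ moderate < t_high ≤ high.  The summary reports cell
    counts and area (in squared grid units) per class.
    """
    t_mod, t_high = thresholds
    if not (0.0 < t_mod < t_high < 1.0):
        raise ValueError(
            f"thresholds must satisfy 0 < t_mod < t_high < 1, got {thresholds}"
        )
    data = surface.data
    cats = np.full(data.shape, np.nan)
    valid = ~np.isnan(data)
    cats[valid] = 0.0
    cats[valid & (data >= t_mod)] = 1.0
    cats[valid & (data >= t_high)] = 2.0

    cell_area = surface.cell_size ** 2
    rows = []
    for code, name in CATEGORIES.items():
        n = int(np.nansum(cats == code))
        rows.append({"class": name, "n_cells": n, "area": n * cell_area})
    summary = pd.DataFrame(rows)
    return StabilityClassification(
        surface.with_data(cats, name="stability_class"), summary, (t_mod, t_high)
    )
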