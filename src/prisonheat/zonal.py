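"""Zonal extraction: polygon + gridded temperature -> per-facility daily series.

Each grid cell is treated as a box centered on its coordinate with half-cell
edges (CF convention). The default mode weights each intersecting cell by
area(polygon ∩ cell) / area(polygon); a polygon too small or degenerate to
intersect any cell interior falls back to the single cell containing its
centroid. Masked (NaN) cells are renormalized out day by day; a facility-day
with no valid cell at all is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .climate import ClimateGrid

__all__ = ["CellWeightMap", "FacilityDailySeries", "cell_weights", "extract_daily_series"]


@dataclass
class CellWeightMap:
    """Sparse polygon->cell weights for one facility.

    entries are ``(row, col, weight)`` with positive weights summing to 1.
    ``mode`` records whether area weighting or the centroid fallback was used.
    """

    facility_id: str
    entries: list
    mode: str = "area"

    def rows(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=int)

    def cols(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=int)

    def weights(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float)


@dataclass
class FacilityDailySeries:
    """Per-facility daily summer temperatures in °F.

    dates is a (T, 3) array of (year, month, day); tmean_f is always
    (tmax_f + tmin_f) / 2, the standard daily mean when only daily extremes
    are available.
    """

    facility_id: str
    dates: np.ndarray
    tmax_f: np.ndarray
    tmin_f: np.ndarray
    tmean_f: np.ndarray

    def years(self) -> np.ndarray:
        return np.unique(self.dates[:, 0])


def cell_weights(
    geometry: BaseGeometry,
    grid: ClimateGrid,
    facility_id: str = "",
    mode: str = "area",
) -> CellWeightMap:
    """Area-overlap weights of grid cells for a facility polygon.

    Parameters
    ----------
    geometry : polygon in the grid's CRS.
    grid : provides cell centers and spacing; values are not used.
    mode : "area" (default) or "centroid" to force centroid sampling.

    Raises
    ------
    ValueError
        If the polygon (or its centroid in fallback mode) lies entirely
        outside the grid extent.
    """
    dy, dx = grid.spacing()
    y, x = grid.y, grid.x
    if mode not in ("area", "centroid"):
        raise ValueError(f"unknown zonal mode: {mode!r}")

    if mode == "area":
        minx, miny, maxx, maxy = geometry.bounds
        # candidate cells: centers within bounds +- half-cell
        ci = np.nonzero((x + dx / 2 > minx) & (x - dx / 2 < maxx))[0]
        ri = np.nonzero((y + dy / 2 > miny) & (y - dy / 2 < maxy))[0]
        entries = []
        total = 0.0
        for r in ri:
            for c in ci:
                cell = box(x[c] - dx / 2, y[r] - dy / 2, x[c] + dx / 2, y[r] + dy / 2)
                a = geometry.intersection(cell).area
                if a > 0:
                    entries.append([int(r), int(c), a])
                    total += a
        if entries:
            entries = [(r, c, a / total) for r, c, a in entries]
            return CellWeightMap(facility_id, entries, mode="area")
        # fall through to centroid fallback for slivers / degenerate polygons

    cx, cy = geometry.centroid.x, geometry.centroid.y
    if not (
        x.min() - dx / 2 <= cx <= x.max() + dx / 2
        and y.min() - dy / 2 <= cy <= y.max() + dy / 2
    ):
        raise ValueError(
            f"facility {facility_id!r}: polygon entirely outside grid extent"
        )
    c = int(np.argmin(np.abs(x - cx)))
    r = int(np.argmin(np.abs(y - cy)))
    return CellWeightMap(facility_id, [(r, c, 1.0)], mode="centroid")


def extract_daily_series(grid: ClimateGrid, weights: CellWeightMap) -> FacilityDailySeries:
    """Weight-average the grid over a facility's cells, day by day.

    The grid must already be in °F. Missing (NaN) cells are dropped and the
    remaining weights renormalized for that day; if every intersecting cell is
    missing on some day, a ValueError names the facility and date.
    """
    if grid.units != "degF":
        raise ValueError("grid must be converted to degF before extraction")
    r, c, w = weights.rows(), weights.cols(), weights.weights()
    tmax_cells = grid.tmax[:, r, c]  # (T, k)
    tmin_cells = grid.tmin[:, r, c]

    valid = ~np.isnan(tmax_cells)
    weff = np.where(valid, w[None, :], 0.0)
    denom = weff.sum(axis=1)
    if np.any(denom == 0):
        t = int(np.argmax(denom == 0))
        y_, m_, d_ = grid.dates[t]
        raise ValueError(
            f"facility {weights.facility_id!r}: all intersecting cells missing "
            f"on {y_}-{m_:02d}-{d_:02d}"
        )
    tmax_f = np.nansum(weff * tmax_cells, axis=1) / denom
    tmin_f = np.nansum(weff * tmin_cells, axis=1) / denom
    return FacilityDailySeries(
        facility_id=weights.facility_id,
        dates=grid.dates.copy(),
        tmax_f=tmax_f,
        tmin_f=tmin_f,
        tmean_f=(tmax_f + tmin_f) / 2.0,
    )
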