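"""Gridded daily temperature: container, NetCDF I/O, summer filtering, units.

The climate container mirrors the conventions of 1-km gridded daily surface
weather products (Daymet-style): daily ``tmax``/``tmin`` fields on a regular
projected grid with a 365-day ("noleap") calendar, so every year has the same
length and the 1 June – 31 August summer window is always 92 days.

Dates are carried as explicit ``(year, month, day)`` integer triples rather
than epoch offsets because standard datetime arithmetic does not apply on a
365-day calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import xarray as xr

__all__ = [
    "ClimateGrid",
    "SUMMER_WINDOW",
    "NOLEAP_MONTH_LENGTHS",
    "noleap_dates",
    "days_in_window",
    "read_climate_grid",
    "write_climate_grid",
    "filter_summer",
    "to_fahrenheit",
    "celsius_to_fahrenheit",
]

#: Month lengths of the 365-day calendar (Feb is always 28; in leap years the
#: source products drop 31 December instead of adding 29 February).
NOLEAP_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

#: Inclusive (month, day) summer window: 1 June through 31 August, 92 days.
SUMMER_WINDOW = ((6, 1), (8, 31))

_F_LABELS = {"degf", "f", "fahrenheit", "degrees fahrenheit", "deg f"}
_C_LABELS = {"degc", "c", "celsius", "degrees c", "degrees celsius", "deg c"}


def _canonical_unit(label: str) -> str:
    low = str(label).strip().lower().replace("_", " ")
    if low in _F_LABELS:
        return "degF"
    if low in _C_LABELS:
        return "degC"
    raise ValueError(f"unknown temperature unit label: {label!r}")


def noleap_dates(year: int) -> np.ndarray:
    """All 365 ``(year, month, day)`` triples of one no-leap calendar year."""
    out = np.empty((365, 3), dtype=np.int64)
    i = 0
    for m, n in enumerate(NOLEAP_MONTH_LENGTHS, start=1):
        out[i : i + n, 0] = year
        out[i : i + n, 1] = m
        out[i : i + n, 2] = np.arange(1, n + 1)
        i += n
    return out


def days_in_window(window=SUMMER_WINDOW) -> int:
    """Number of calendar days inside an inclusive (month, day) window."""
    dates = noleap_dates(2000)
    return int(_window_mask(dates, window).sum())


def _window_mask(dates: np.ndarray, window) -> np.ndarray:
    (m0, d0), (m1, d1) = window
    if (m0, d0) > (m1, d1):
        raise ValueError("window start must not be after window end")
    md = dates[:, 1] * 100 + dates[:, 2]
    return (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)


@dataclass
class ClimateGrid:
    """Daily tmax/tmin fields on a regular projected grid.

    Attributes
    ----------
    dates : (T, 3) int array of (year, month, day) on a 365-day calendar.
    y, x : 1-D projected coordinates of cell centers, regular spacing.
    tmax, tmin : (T, ny, nx) float arrays in ``units``; NaN marks masked cells.
    units : "degC" or "degF".
    crs : free-form coordinate reference descriptor (no reprojection is done;
        facility geometries must share this CRS).
    """

    dates: np.ndarray
    y: np.ndarray
    x: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    units: str
    crs: str = "local-projected"
    calendar: str = "noleap"

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.units = _canonical_unit(self.units)

    # -- basic queries -----------------------------------------------------
    @property
    def n_time(self) -> int:
        return self.dates.shape[0]

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates[:, 0])

    def spacing(self) -> tuple[float, float]:
        """(dy, dx) cell spacing; raises if the grid is irregular."""
        dy = _regular_step(self.y, "y")
        dx = _regular_step(self.x, "x")
        return dy, dx

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on the first breach."""
        if self.tmax.shape != (self.n_time, self.y.size, self.x.size):
            raise ValueError("tmax shape does not match (time, y, x) coords")
        if self.tmin.shape != self.tmax.shape:
            raise ValueError("tmin and tmax shapes differ")
        self.spacing()
        key = self.dates[:, 0] * 10000 + self.dates[:, 1] * 100 + self.dates[:, 2]
        if np.any(np.diff(key) <= 0):
            i = int(np.argmax(np.diff(key) <= 0))
            raise ValueError(f"time not strictly increasing at index {i + 1}")
        bad = np.asarray(self.tmax < self.tmin)
        if bad.any():
            t, iy, ix = np.unravel_index(int(np.argmax(bad)), bad.shape)
            y_, m_, d_ = self.dates[t]
            raise ValueError(
                f"tmax < tmin at time index {t} ({y_}-{m_:02d}-{d_:02d}), "
                f"cell (row={iy}, col={ix})"
            )


def _regular_step(coord: np.ndarray, name: str) -> float:
    if coord.size < 2:
        return 1.0
    steps = np.diff(coord)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{name} coordinate spacing is irregular")
    return float(abs(steps[0]))


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style dims time/y/x; scipy backend writes NetCDF3 classic)
# ---------------------------------------------------------------------------

def grid_to_dataset(grid: ClimateGrid) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "tmax": (("time", "y", "x"), grid.tmax, {"units": grid.units}),
            "tmin": (("time", "y", "x"), grid.tmin, {"units": grid.units}),
        },
        coords={
            "time": ("time", np.arange(grid.n_time, dtype=np.int32)),
            "year": ("time", grid.dates[:, 0].astype(np.int32)),
            "month": ("time", grid.dates[:, 1].astype(np.int32)),
            "day": ("time", grid.dates[:, 2].astype(np.int32)),
            "y": ("y", grid.y),
            "x": ("x", grid.x),
        },
        attrs={"calendar": grid.calendar, "crs": grid.crs},
    )
    return ds


def write_climate_grid(grid: ClimateGrid, path) -> None:
    """Write one grid (any time span) to a NetCDF file."""
    grid_to_dataset(grid).to_netcdf(path, engine="scipy")


def read_climate_grid(paths, variables: dict | None = None) -> ClimateGrid:
    """Read one or more per-period NetCDF files into a single ClimateGrid.

    Parameters
    ----------
    paths : ordered sequence of file paths sharing grid geometry and CRS.
    variables : optional name mapping, e.g. ``{"tmax": "tasmax"}`` when the
        file stores the fields under different variable names.

    Raises
    ------
    ValueError
        On inconsistent grids across files, missing variables, missing unit
        metadata, or a cell-day with tmax < tmin.
    """
    names = {"tmax": "tmax", "tmin": "tmin"}
    if variables:
        names.update(variables)
    paths = list(paths)
    if not paths:
        raise ValueError("no climate files given")

    pieces = []
    ref = None
    for p in paths:
        with xr.open_dataset(p, engine="scipy", decode_times=False) as ds:
            ds = ds.load()
        for role in ("tmax", "tmin"):
            if names[role] not in ds:
                raise ValueError(f"variable {names[role]!r} not found in {p}")
        for coord in ("year", "month", "day"):
            if coord not in ds.coords and coord not in ds:
                raise ValueError(f"calendar coordinate {coord!r} missing in {p}")
        unit_attr = ds[names["tmax"]].attrs.get("units")
        if unit_attr is None:
            raise ValueError(f"missing unit metadata on {names['tmax']!r} in {p}")
        unit = _canonical_unit(unit_attr)
        geom = (ds["y"].values, ds["x"].values, unit, ds.attrs.get("crs", "local-projected"))
        if ref is None:
            ref = geom
        else:
            if geom[0].shape != ref[0].shape or not (
                np.allclose(geom[0], ref[0]) and np.allclose(geom[1], ref[1])
            ):
                raise ValueError(f"grid geometry in {p} differs from first file")
            if geom[2] != ref[2]:
                raise ValueError(f"unit in {p} differs from first file")
        pieces.append(ds)

    dates = np.concatenate(
        [
            np.stack(
                [ds["year"].values, ds["month"].values, ds["day"].values], axis=1
            )
            for ds in pieces
        ]
    )
    tmax = np.concatenate([ds[names["tmax"]].values for ds in pieces], axis=0)
    tmin = np.concatenate([ds[names["tmin"]].values for ds in pieces], axis=0)
    grid = ClimateGrid(
        dates=dates,
        y=ref[0],
        x=ref[1],
        tmax=tmax,
        tmin=tmin,
        units=ref[2],
        crs=ref[3],
        calendar=pieces[0].attrs.get("calendar", "noleap"),
    )
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# Summer filtering and units
# ---------------------------------------------------------------------------

def filter_summer(grid: ClimateGrid, window=SUMMER_WINDOW) -> ClimateGrid:
    """Keep only days whose (month, day) falls in the inclusive window.

    The per-year day count is identical across years on the 365-day calendar.
    Idempotent: filtering an already-filtered grid is a no-op.
    """
    mask = _window_mask(grid.dates, window)
    if not mask.any():
        raise ValueError("summer filter produced an empty grid")
    return replace(
        grid,
        dates=grid.dates[mask],
        tmax=grid.tmax[mask],
        tmin=grid.tmin[mask],
    )


def celsius_to_fahrenheit(values):
    """F = C * 9/5 + 32, elementwise."""
    return np.asarray(values, dtype=float) * 9.0 / 5.0 + 32.0


def to_fahrenheit(grid: ClimateGrid) -> ClimateGrid:
    """Convert a grid to °F; identity if already in °F."""
    if grid.units == "degF":
        return grid
    return replace(
        grid,
        tmax=celsius_to_fahrenheit(grid.tmax),
        tmin=celsius_to_fahrenheit(grid.tmin),
        units="degF",
    )
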