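"""Synthetic climate grids and facility cohorts with known ground truth.

The generator emulates the three inputs of a facility heat-exposure study —
a Daymet-style gridded daily temperature product, facility boundary polygons,
and a census-style facility attribute table — so every downstream stage can
be tested without downloads and recovered against closed-form expectations.

Climate model per cell-day (all in °F; unit conversion is an I/O concern
tested separately so that ground-truth arithmetic stays exact):

    daily_mean = base(cell) + seasonal(day) + trend · (year − first_year)
                 + heatwave(day, year) + noise
    tmax = daily_mean + diurnal_range / 2
    tmin = daily_mean − diurnal_range / 2

The seasonal term is a half-sine over the 92-day summer window (zero outside
it); any smooth shape would do since per-year identical shapes cancel in the
anomaly and are integrated out in expectations. The calendar is no-leap: 365
days every year, so the summer window is always 92 days.

Facilities are axis-aligned rectangles (area weights exactly computable by
hand), placed in a "cool" west half or "hot" east half of the grid so that
demographic or characteristic associations with exposure can be planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box, mapping

from .climate import (
    SUMMER_WINDOW,
    ClimateGrid,
    _window_mask,
    noleap_dates,
    write_climate_grid,
)
from .facilities import CENSUS_CATEGORIES, CHARACTERISTIC_KINDS

__all__ = [
    "ClimateSimConfig",
    "CohortSimConfig",
    "ExposureAssociation",
    "generate_climate",
    "write_climate_per_year",
    "generate_facilities",
    "expected_metrics",
    "two_zone_base",
]

SUMMER_DAYS = 92

#: Default per-region demographic mixes over the eight census categories,
#: loosely shaped like US prison demographics; the hot region carries a
#: larger Hispanic share so equity contrasts have a planted direction.
DEFAULT_MIXES = {
    "cool": (0.30, 0.33, 0.23, 0.02, 0.01, 0.005, 0.015, 0.09),
    "hot": (0.25, 0.28, 0.33, 0.02, 0.01, 0.005, 0.015, 0.09),
}

#: Default prevalence of each binary characteristic and level probabilities
#: of the categorical ones (rare functions rare, court orders uncommon).
DEFAULT_PREVALENCE = {
    "geriatric_unit": 0.08,
    "poor_crowding": 0.05,
    "poor_mental_health": 0.06,
    "poor_medical": 0.06,
    "poor_disability_accommodations": 0.04,
    "poor_disciplinary": 0.03,
    "poor_grievance": 0.04,
    "poor_staffing": 0.05,
    "poor_totality": 0.04,
    "work_agriculture": 0.15,
    "function_medical": 0.06,
    "function_mental_health": 0.05,
    "function_geriatric": 0.02,
    "function_boot_camp": 0.02,
    "security_level": (0.40, 0.30, 0.30),
    "percent_leave": (0.25, 0.35, 0.40),
    "operator": (0.85, 0.15),
}

STATES_BY_REGION = {"cool": ("WA", "OR", "ME", "MN"), "hot": ("AZ", "TX", "NV", "CA")}


@dataclass
class ClimateSimConfig:
    """Parameters of the synthetic daily temperature generator (°F)."""

    grid_ny: int = 6
    grid_nx: int = 6
    cell_size: float = 1000.0  # meters
    origin: tuple = (0.0, 0.0)  # projected x, y of the first cell center
    years: tuple = (1990, 2023)  # inclusive
    base_field: float | np.ndarray = 80.0  # climatological summer-mean tmean
    seasonal_amplitude: float = 6.0
    diurnal_range: float = 20.0  # tmax − tmin
    trend: float = 0.05  # °F per year, uniform
    heatwave_events: list = field(default_factory=list)  # (year, start, len, amp)
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.grid_ny <= 0 or self.grid_nx <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("years range is empty")
        for ev in self.heatwave_events:
            year, start, length, _amp = ev
            if not (y0 <= year <= y1):
                raise ValueError(f"heatwave year {year} outside simulated years")
            if start < 0 or length < 1 or start + length > SUMMER_DAYS:
                raise ValueError(
                    f"heatwave ({year}, {start}, {length}) outside the "
                    f"{SUMMER_DAYS}-day summer window"
                )

    def base_array(self) -> np.ndarray:
        base = np.asarray(self.base_field, dtype=float)
        if base.ndim == 0:
            base = np.full((self.grid_ny, self.grid_nx), float(base))
        if base.shape != (self.grid_ny, self.grid_nx):
            raise ValueError("base_field shape does not match grid dimensions")
        return base

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        x = x0 + np.arange(self.grid_nx) * self.cell_size
        y = y0 + np.arange(self.grid_ny) * self.cell_size
        return y, x


@dataclass
class ExposureAssociation:
    """Plant a characteristic–exposure link: facilities holding ``level`` of
    ``variable`` are placed in the hot east half with probability
    ``hot_probability`` (others with ``baseline_hot_probability``)."""

    variable: str
    level: str = "yes"
    hot_probability: float = 1.0
    baseline_hot_probability: float = 0.5

    def __post_init__(self):
        for p in (self.hot_probability, self.baseline_hot_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic facility cohort generator."""

    n_facilities: int = 12
    polygon_size_range: tuple = (0.4, 1.6)  # rectangle side lengths, in cells
    demographic_mixes: dict = field(default_factory=lambda: dict(DEFAULT_MIXES))
    characteristic_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    exposure_association: ExposureAssociation | None = None
    missingness_rate: float = 0.0
    total_population_range: tuple = (150, 2500)
    seed: int = 0

    def __post_init__(self):
        if self.n_facilities < 1:
            raise ValueError("n_facilities must be positive")
        if not 0 <= self.missingness_rate <= 1:
            raise ValueError("missingness_rate must be in [0, 1]")
        lo, hi = self.polygon_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid polygon_size_range")
        for region, mix in self.demographic_mixes.items():
            mix = np.asarray(mix, dtype=float)
            if mix.size != len(CENSUS_CATEGORIES):
                raise ValueError(f"mix for {region!r} must have 8 entries")
            if (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
                raise ValueError(f"mix for {region!r} must be a probability vector")
        for var, p in self.characteristic_prevalence.items():
            probs = np.atleast_1d(np.asarray(p, dtype=float))
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"prevalence for {var!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# Climate generation
# ---------------------------------------------------------------------------

def _seasonal_profile(dates: np.ndarray, amplitude: float, window=SUMMER_WINDOW):
    """Half-sine bump over the summer window, zero elsewhere; (T,) array."""
    seas = np.zeros(dates.shape[0])
    mask = _window_mask(dates, window)
    idx = np.flatnonzero(mask)
    # day-of-summer index resets each year
    years = dates[idx, 0]
    day_of_summer = np.concatenate(
        [np.arange(np.sum(years == y)) for y in np.unique(years)]
    )
    n = SUMMER_DAYS - 1
    seas[idx] = amplitude * np.sin(np.pi * day_of_summer / n)
    return seas, mask, idx, day_of_summer


def daily_mean_field(config: ClimateSimConfig, noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(dates, mean) with mean of shape (T, ny, nx); noise optional."""
    y0, y1 = config.years
    dates = np.concatenate([noleap_dates(y) for y in range(y0, y1 + 1)])
    base = config.base_array()
    seas, _, sidx, dos = _seasonal_profile(dates, config.seasonal_amplitude)
    mean = base[None, :, :] + seas[:, None, None]
    mean += config.trend * (dates[:, 0] - y0)[:, None, None]
    for year, start, length, amp in config.heatwave_events:
        sel = sidx[(dates[sidx, 0] == year) & (dos >= start) & (dos < start + length)]
        mean[sel] += amp
    if noise and config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        mean = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    return dates, mean


def generate_climate(config: ClimateSimConfig, out_dir=None) -> ClimateGrid:
    """Generate the full multi-year grid; optionally write per-year files.

    Reproducible: the same config (including seed) yields bit-identical
    fields and, via ``write_climate_per_year``, byte-identical files.
    """
    dates, mean = daily_mean_field(config, noise=True)
    half = config.diurnal_range / 2.0
    y, x = config.coords()
    grid = ClimateGrid(
        dates=dates,
        y=y,
        x=x,
        tmax=mean + half,
        tmin=mean - half,
        units="degF",
        crs="synthetic-projected-meters",
    )
    grid.validate()
    if out_dir is not None:
        write_climate_per_year(grid, out_dir, config=config)
    return grid


def write_climate_per_year(grid: ClimateGrid, out_dir, config=None, prefix="climate"):
    """Write one NetCDF file per year plus a JSON config/seed sidecar.

    Returns the ordered list of file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for year in grid.years:
        mask = grid.dates[:, 0] == year
        sub = ClimateGrid(
            dates=grid.dates[mask],
            y=grid.y,
            x=grid.x,
            tmax=grid.tmax[mask],
            tmin=grid.tmin[mask],
            units=grid.units,
            crs=grid.crs,
        )
        p = out_dir / f"{prefix}_{year}.nc"
        write_climate_grid(sub, p)
        paths.append(p)
    if config is not None:
        sidecar = {k: _jsonable(v) for k, v in asdict(config).items()}
        sidecar["seasonal_shape"] = "half-sine over 92-day summer window"
        (out_dir / f"{prefix}_config.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    return v


# ---------------------------------------------------------------------------
# Facility cohort generation
# ---------------------------------------------------------------------------

def two_zone_base(ny: int, nx: int, cool: float = 80.0, hot: float = 86.0) -> np.ndarray:
    """Base field with a cool west half and a hot east half (°F)."""
    base = np.full((ny, nx), cool, dtype=float)
    base[:, nx // 2 :] = hot
    return base


def generate_facilities(
    config: CohortSimConfig, grid: ClimateGrid, out_dir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rectangular facility polygons plus a census-style attribute table.

    Returns ``(vector, attributes)``: the vector frame has facility_id, name,
    state and shapely geometry; the attribute frame has the eight demographic
    counts, total and staff population, and the 17 characteristics. Facilities
    selected by ``missingness_rate`` have all race/ethnicity counts blanked.
    When ``out_dir`` is given, writes GeoJSON, CSV and a JSON config sidecar.
    """
    rng = np.random.default_rng(config.seed)
    dy, dx = (grid.spacing() if grid.y.size > 1 or grid.x.size > 1 else (1.0, 1.0))
    xmin, xmax = grid.x.min() - dx / 2, grid.x.max() + dx / 2
    ymin, ymax = grid.y.min() - dy / 2, grid.y.max() + dy / 2
    xmid = (xmin + xmax) / 2

    lo, hi = config.polygon_size_range
    max_side = hi * max(dx, dy)
    if max_side > (xmax - xmin) / 2 or max_side > (ymax - ymin):
        raise ValueError("polygon size range too large for the grid extent")

    # characteristics first: region placement may depend on them
    n = config.n_facilities
    attrs = {}
    for var, kind in CHARACTERISTIC_KINDS.items():
        p = config.characteristic_prevalence.get(var)
        if kind == "binary":
            attrs[var] = np.where(rng.random(n) < float(p), "yes", "no")
        else:
            levels = list(kind)
            probs = np.asarray(p, dtype=float)
            probs = probs / probs.sum()
            attrs[var] = rng.choice(levels, size=n, p=probs)

    assoc = config.exposure_association
    if assoc is not None:
        has = attrs[assoc.variable] == assoc.level
        p_hot = np.where(has, assoc.hot_probability, assoc.baseline_hot_probability)
    else:
        p_hot = np.full(n, 0.5)
    hot = rng.random(n) < p_hot

    vec_rows, attr_rows = [], []
    missing = rng.random(n) < config.missingness_rate
    for i in range(n):
        region = "hot" if hot[i] else "cool"
        w = rng.uniform(lo, hi) * dx
        h = rng.uniform(lo, hi) * dy
        if region == "hot":
            x0 = rng.uniform(xmid, xmax - w)
        else:
            x0 = rng.uniform(xmin, xmid - w)
        y0 = rng.uniform(ymin, ymax - h)
        geom = box(x0, y0, x0 + w, y0 + h)
        fid = f"F{i:04d}"
        state = rng.choice(STATES_BY_REGION[region])
        vec_rows.append(
            {"facility_id": fid, "name": f"Synthetic Facility {i}", "state": state,
             "region": region, "geometry": geom}
        )
        mix = np.asarray(config.demographic_mixes.get(region, DEFAULT_MIXES[region]))
        total = int(rng.integers(*config.total_population_range))
        counts = rng.multinomial(total, mix / mix.sum())
        row = {"facility_id": fid, "state": state, "jurisdiction": "state",
               "total_population": total,
               "staff_population": int(round(total * 0.3))}
        for cat, cnt in zip(CENSUS_CATEGORIES, counts):
            row[cat] = np.nan if missing[i] else int(cnt)
        for var in CHARACTERISTIC_KINDS:
            row[var] = attrs[var][i]
        attr_rows.append(row)

    vector = pd.DataFrame(vec_rows)
    attributes = pd.DataFrame(attr_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_facilities_geojson(vector, out_dir / "facilities.geojson")
        attributes.to_csv(out_dir / "attributes.csv", index=False)
        sidecar = {
            k: _jsonable(v)
            for k, v in asdict(config).items()
            if k != "exposure_association"
        }
        if config.exposure_association is not None:
            sidecar["exposure_association"] = asdict(config.exposure_association)
        (out_dir / "cohort_config.json").write_text(json.dumps(sidecar, indent=2))
    return vector, attributes


def write_facilities_geojson(vector: pd.DataFrame, path):
    feats = []
    for _, row in vector.iterrows():
        props = {k: v for k, v in row.items() if k != "geometry"}
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(row["geometry"])}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1)
    )


# ---------------------------------------------------------------------------
# Closed-form expectations (recovery targets)
# ---------------------------------------------------------------------------

def expected_metrics(
    config: ClimateSimConfig,
    facility_base: dict,
    analysis_years=(2020, 2023),
    baseline_years=(1990, 2019),
    threshold: float = 85.0,
    risk_offset: float = 10.0,
) -> pd.DataFrame:
    """Analytic expectations of the four metrics under the generator.

    ``facility_base`` maps facility_id to the facility's area-weighted base
    value (°F). Exact results: the expected anomaly is
    ``trend × (mean(analysis years) − mean(baseline years))`` for any noise
    level, because per-year noise distributions are identical and cancel; the
    expected exceedance counts use the Gaussian day-by-day exceedance
    probability Φ((μ_d − threshold)/σ) (exact for days-above; the risk-day
    baseline mean is treated as known, a vanishing O(σ/√(92·years))
    approximation). The expected p90 is the per-summer p90 of the noise-free
    daily means — exact at σ = 0, first-order otherwise.
    """
    y0 = config.years[0]
    a_years = np.arange(analysis_years[0], analysis_years[-1] + 1)
    b_years = np.arange(baseline_years[0], baseline_years[-1] + 1)
    exp_anomaly = config.trend * (a_years.mean() - b_years.mean())

    dates, mean0 = daily_mean_field(config, noise=False)
    # mean0 is constant across cells up to base; summer profile per year:
    summer = _window_mask(dates, SUMMER_WINDOW)
    rows = []
    for fid, base in facility_base.items():
        # per-day noise-free mean for this facility = base + shared terms
        shared = mean0[:, 0, 0] - config.base_array()[0, 0]
        mu = base + shared
        # days above threshold (daily mean), per analysis summer
        exp_days, exp_p90s = [], []
        for y in a_years:
            m = summer & (dates[:, 0] == y)
            mu_y = mu[m]
            if config.noise_sd > 0:
                probs = stats.norm.sf(threshold, loc=mu_y, scale=config.noise_sd)
                exp_days.append(probs.sum())
            else:
                exp_days.append(np.sum(mu_y > threshold))
            exp_p90s.append(np.quantile(mu_y, 0.9, method="linear"))
        # risk days: baseline mean over baseline summers, noise-free
        mb = summer & np.isin(dates[:, 0], b_years)
        base_mean = mu[mb].mean()
        exp_risk = 0.0
        for y in a_years:
            m = summer & (dates[:, 0] == y)
            mu_y = mu[m]
            if config.noise_sd > 0:
                exp_risk += stats.norm.sf(
                    base_mean + risk_offset, loc=mu_y, scale=config.noise_sd
                ).sum()
            else:
                exp_risk += float(np.sum(mu_y > base_mean + risk_offset))
        rows.append(
            {
                "facility_id": fid,
                "expected_days_above": float(np.mean(exp_days)),
                "expected_p90_tmax": float(
                    np.mean(exp_p90s) + config.diurnal_range / 2.0
                ),
                "expected_anomaly": float(exp_anomaly),
                "expected_risk_days": float(exp_risk),
            }
        )
    return pd.DataFrame(rows).set_index("facility_id")
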