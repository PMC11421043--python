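import numpy as np
import pytest

from prisonheat.climate import SUMMER_WINDOW, _window_mask, noleap_dates
from prisonheat.zonal import FacilityDailySeries


def summer_dates(year: int) -> np.ndarray:
    d = noleap_dates(year)
    return d[_window_mask(d, SUMMER_WINDOW)]


def make_series(tmean_by_year, fid="F0", diurnal=0.0, tmax_by_year=None):
    """Build a per-facility daily summer series from per-year value arrays.

    ``tmean_by_year`` maps year -> daily-mean values (length 92 or a scalar);
    tmax/tmin are tmean +- diurnal/2 unless ``tmax_by_year`` overrides tmax.
    """
    dates, tmean, tmax = [], [], []
    for year in sorted(tmean_by_year):
        d = summer_dates(year)
        v = np.broadcast_to(np.asarray(tmean_by_year[year], dtype=float), (len(d),)).copy()
        dates.append(d)
        tmean.append(v)
        if tmax_by_year is not None:
            tmax.append(
                np.broadcast_to(
                    np.asarray(tmax_by_year[year], dtype=float), (len(d),)
                ).copy()
            )
        else:
            tmax.append(v + diurnal / 2.0)
    dates = np.concatenate(dates)
    tmean = np.concatenate(tmean)
    tmax = np.concatenate(tmax)
    tmin = 2 * tmean - tmax
    return FacilityDailySeries(
        facility_id=fid, dates=dates, tmax_f=tmax, tmin_f=tmin, tmean_f=tmean
    )


@pytest.fixture(scope="session")
def flat_config():
    from prisonheat.synthetic import ClimateSimConfig

    return ClimateSimConfig(
        grid_ny=3,
        grid_nx=3,
        years=(2000, 2003),
        base_field=80.0,
        seasonal_amplitude=0.0,
        diurnal_range=0.0,
        trend=0.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def flat_grid(flat_config):
    from prisonheat.synthetic import generate_climate

    return generate_climate(flat_config)


@pytest.fixture(scope="session")
def synthetic_inputs(tmp_path_factory):
    """A small written bundle: per-year climate files + facility files."""
    from prisonheat.synthetic import (
        ClimateSimConfig,
        CohortSimConfig,
        generate_climate,
        generate_facilities,
        two_zone_base,
    )

    d = tmp_path_factory.mktemp("synth")
    cfg = ClimateSimConfig(
        grid_ny=6,
        grid_nx=6,
        years=(1990, 2023),
        base_field=two_zone_base(6, 6),
        seed=7,
    )
    grid = generate_climate(cfg, out_dir=d)
    ccfg = CohortSimConfig(n_facilities=12, seed=8, missingness_rate=0.1)
    generate_facilities(ccfg, grid, out_dir=d)
    paths = sorted(d.glob("climate_*.nc"))
    return {
        "dir": d,
        "climate_config": cfg,
        "cohort_config": ccfg,
        "grid": grid,
        "climate_paths": [str(p) for p in paths],
        "vector": str(d / "facilities.geojson"),
        "attributes": str(d / "attributes.csv"),
    }
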