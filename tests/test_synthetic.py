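import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prisonheat.climate import filter_summer
from prisonheat.facilities import CENSUS_CATEGORIES, apply_cohort_filters
from prisonheat.metrics import compute_metrics
from prisonheat.risk_tests import compare_binary
from prisonheat.synthetic import (
    ClimateSimConfig,
    CohortSimConfig,
    ExposureAssociation,
    expected_metrics,
    generate_climate,
    generate_facilities,
    two_zone_base,
    write_climate_per_year,
)
from prisonheat.zonal import cell_weights, extract_daily_series


def test_degenerate_generator_is_exactly_flat(flat_grid):
    """noise 0, trend 0, amplitude 0, flat base 80 -> every cell-day mean is 80."""
    tmean = (flat_grid.tmax + flat_grid.tmin) / 2.0
    assert np.all(tmean == 80.0)


def test_trend_is_exactly_linear():
    cfg = ClimateSimConfig(
        grid_ny=2,
        grid_nx=2,
        years=(2000, 2004),
        base_field=80.0,
        seasonal_amplitude=0.0,
        diurnal_range=10.0,
        trend=0.5,
        noise_sd=0.0,
        seed=0,
    )
    g = generate_climate(cfg)
    tmean = (g.tmax + g.tmin) / 2.0
    for i, year in enumerate(range(2000, 2005)):
        vals = tmean[g.dates[:, 0] == year]
        assert np.all(vals == 80.0 + 0.5 * i)
    assert np.all(g.tmax - g.tmin == 10.0)


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = ClimateSimConfig(grid_ny=3, grid_nx=3, years=(2000, 2001), seed=42)
    for sub in ("a", "b"):
        write_climate_per_year(generate_climate(cfg), tmp_path / sub, config=cfg)
    for name in ("climate_2000.nc", "climate_2001.nc", "climate_config.json"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)


def test_calendar_and_ordering_invariants(synthetic_inputs):
    g = synthetic_inputs["grid"]
    years, counts = np.unique(g.dates[:, 0], return_counts=True)
    assert list(counts) == [365] * 34
    assert filter_summer(g).n_time == 92 * 34
    assert np.all(g.tmax >= g.tmin)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"grid_ny": 0},
        {"grid_nx": -1},
        {"noise_sd": -0.1},
        {"diurnal_range": -1.0},
        {"years": (2005, 2000)},
        {"heatwave_events": [(2001, 90, 5, 10.0)]},  # runs past the 92-day window
        {"heatwave_events": [(1980, 0, 5, 10.0)]},  # year not simulated
    ],
)
def test_invalid_climate_configs_rejected(kwargs):
    base = dict(grid_ny=2, grid_nx=2, years=(2000, 2002))
    base.update(kwargs)
    with pytest.raises(ValueError):
        ClimateSimConfig(**base)


def test_zero_missingness_passes_completeness_filter(flat_grid):
    vec, attrs = generate_facilities(
        CohortSimConfig(n_facilities=20, missingness_rate=0.0,
                        polygon_size_range=(0.3, 0.8), seed=1), flat_grid
    )
    df = vec.merge(attrs.drop(columns="state"), on="facility_id").set_index("facility_id")
    df["attributes_missing"] = False
    kept, log = apply_cohort_filters(df, ["require-complete-demographics"])
    assert len(kept) == 20 and log.final_count == 20


def test_missingness_blanks_all_eight_categories(flat_grid):
    _, attrs = generate_facilities(
        CohortSimConfig(n_facilities=200, missingness_rate=0.25,
                        polygon_size_range=(0.3, 0.8), seed=2), flat_grid
    )
    demog = attrs[list(CENSUS_CATEGORIES)]
    row_missing = demog.isna().any(axis=1)
    # missingness is all-or-nothing per facility
    assert (demog[row_missing].isna().all(axis=1)).all()
    assert 0.15 < row_missing.mean() < 0.35


def test_polygons_lie_inside_grid_extent_and_ids_unique(synthetic_inputs):
    g = synthetic_inputs["grid"]
    vec, attrs = generate_facilities(
        CohortSimConfig(n_facilities=40, seed=3), g
    )
    dy, dx = g.spacing()
    assert vec["facility_id"].is_unique
    assert set(vec["facility_id"]) == set(attrs["facility_id"])
    for geom in vec["geometry"]:
        x0, y0, x1, y1 = geom.bounds
        assert x0 >= g.x.min() - dx / 2 and x1 <= g.x.max() + dx / 2
        assert y0 >= g.y.min() - dy / 2 and y1 <= g.y.max() + dy / 2


def test_oversized_polygons_rejected(flat_grid):
    with pytest.raises(ValueError, match="polygon size"):
        generate_facilities(
            CohortSimConfig(n_facilities=2, polygon_size_range=(5.0, 10.0)), flat_grid
        )


def test_invalid_cohort_configs_rejected():
    with pytest.raises(ValueError):
        CohortSimConfig(n_facilities=0)
    with pytest.raises(ValueError):
        CohortSimConfig(missingness_rate=1.5)
    with pytest.raises(ValueError):
        CohortSimConfig(demographic_mixes={"hot": (0.5, 0.5, 0, 0, 0, 0, 0, 0.2)})


def test_expected_anomaly_is_seventeen_times_trend():
    cfg = ClimateSimConfig(grid_ny=2, grid_nx=2, years=(1990, 2023), trend=0.1, noise_sd=1.0)
    tab = expected_metrics(cfg, {"F0": 80.0})
    # mean(2020..2023) - mean(1990..2019) = 2021.5 - 2004.5 = 17
    assert tab.loc["F0", "expected_anomaly"] == pytest.approx(1.7)


def test_expected_days_above_zero_for_flat_80(flat_config):
    tab = expected_metrics(
        flat_config, {"F0": 80.0}, analysis_years=(2002, 2003), baseline_years=(2000, 2001)
    )
    assert tab.loc["F0", "expected_days_above"] == 0.0
    assert tab.loc["F0", "expected_p90_tmax"] == 80.0


def test_single_heatwave_yields_exactly_its_length_in_risk_days():
    """Flat 80 deg generator, one 5-day +15 deg heatwave in 2021: the baseline mean
    is 80, so exactly those 5 days exceed baseline + 10."""
    cfg = ClimateSimConfig(
        grid_ny=2,
        grid_nx=2,
        years=(1990, 2023),
        base_field=80.0,
        seasonal_amplitude=0.0,
        diurnal_range=0.0,
        trend=0.0,
        noise_sd=0.0,
        heatwave_events=[(2021, 10, 5, 15.0)],
    )
    tab = expected_metrics(cfg, {"F0": 80.0})
    assert tab.loc["F0", "expected_risk_days"] == 5.0
    # and the realized pipeline metric agrees
    grid = filter_summer(generate_climate(cfg))
    from shapely.geometry import box

    geom = box(grid.x[0] - 500, grid.y[0] - 500, grid.x[0] + 500, grid.y[0] + 500)
    s = extract_daily_series(grid, cell_weights(geom, grid, "F0"))
    rec = compute_metrics(s, (2020, 2023), (1990, 2019))
    assert rec.risk_days == 5


def test_planted_association_recovered_by_binary_comparison():
    """Facilities with agricultural work placed in a hot subregion >=5 degF
    warmer are recovered as significantly hotter; the p-value of the package's
    own comparison is cross-checked against a direct scipy Welch test."""
    cfg = ClimateSimConfig(
        grid_ny=8,
        grid_nx=8,
        years=(2019, 2019),
        base_field=two_zone_base(8, 8, cool=80.0, hot=86.0),
        noise_sd=1.0,
        trend=0.0,
        seed=5,
    )
    grid = filter_summer(generate_climate(cfg))
    prev = dict(work_agriculture=0.5)
    ccfg = CohortSimConfig(
        n_facilities=70,
        characteristic_prevalence={**CohortSimConfig().characteristic_prevalence, **prev},
        exposure_association=ExposureAssociation(
            "work_agriculture", "yes", hot_probability=1.0, baseline_hot_probability=0.0
        ),
        seed=6,
    )
    vec, attrs = generate_facilities(ccfg, grid)
    expo = {}
    for _, row in vec.iterrows():
        s = extract_daily_series(grid, cell_weights(row["geometry"], grid, row["facility_id"]))
        expo[row["facility_id"]] = np.quantile(s.tmax_f[s.dates[:, 0] == 2019], 0.9)
    merged = attrs.set_index("facility_id")
    merged["expo"] = pd.Series(expo)
    yes = merged.loc[merged["work_agriculture"] == "yes", "expo"].to_numpy()
    no = merged.loc[merged["work_agriculture"] == "no", "expo"].to_numpy()
    assert min(len(yes), len(no)) >= 30
    res = compare_binary("work_agriculture", {"yes": yes, "no": no})
    assert res.significant and res.difference > 0
    assert res.difference == pytest.approx(6.0, abs=1.5)
    if res.test_used == "t":
        oracle = stats.ttest_ind(yes, no, equal_var=False)
        assert res.p_value == pytest.approx(float(oracle.pvalue))


def test_single_facility_cohort_is_degenerate_downstream(flat_grid):
    from prisonheat.risk_tests import run_battery

    vec, attrs = generate_facilities(CohortSimConfig(n_facilities=1, polygon_size_range=(0.3, 0.8), seed=9), flat_grid)
    attrs = attrs.assign(p90_tmax=90.0)
    results = run_battery(attrs)
    assert all(r.test_used == "untestable" for r in results)
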