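import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prisonheat.metrics import (
    compute_metrics,
    exceedance_share,
    mean_annual_days_above,
    metrics_table,
    multi_year_p90,
    p90_anomaly,
    risk_days,
    state_summary,
    summer_p90,
)
from conftest import make_series


def test_all_hot_days_give_ninety_two():
    s = make_series({y: 90.0 for y in range(2020, 2024)})
    mean_days, any_day = mean_annual_days_above(s, 85.0, (2020, 2023))
    assert mean_days == 92.0 and any_day


def test_boundary_days_excluded_by_strict_inequality():
    s = make_series({y: 85.0 for y in range(2020, 2024)})
    mean_days, any_day = mean_annual_days_above(s, 85.0, (2020, 2023))
    assert mean_days == 0.0 and not any_day


def test_day_count_matches_brute_force_enumeration():
    rng = np.random.default_rng(3)
    vals = {y: rng.normal(84, 4, 92) for y in range(2020, 2024)}
    s = make_series(vals)
    mean_days, _ = mean_annual_days_above(s, 85.0, (2020, 2023))
    manual = np.mean([sum(1 for v in vals[y] if v > 85.0) for y in vals])
    assert mean_days == manual


def test_missing_summer_is_an_error():
    s = make_series({2020: 90.0})
    with pytest.raises(ValueError, match="no data for summer 2021"):
        mean_annual_days_above(s, 85.0, (2020, 2021))


def test_p90_of_constant_series_is_the_constant():
    assert summer_p90(np.full(92, 77.3)) == 77.3


def test_p90_linear_interpolation_rule():
    # sorted rank position 1 + 0.9*(92-1) = 82.9 -> 82 + 0.9*(83-82)
    assert summer_p90(np.arange(1.0, 93.0)) == pytest.approx(82.9)
    # cross-check against an independent percentile routine
    from scipy.stats import scoreatpercentile

    x = np.random.default_rng(0).normal(90, 5, 92)
    assert summer_p90(x) == pytest.approx(
        scoreatpercentile(x, 90, interpolation_method="fraction")
    )


@settings(max_examples=30, deadline=None)
@given(
    a=st.floats(0.1, 3.0),
    b=st.floats(-20.0, 20.0),
    seed=st.integers(0, 2**16),
)
def test_p90_affine_equivariance(a, b, seed):
    x = np.random.default_rng(seed).normal(90, 5, 60)
    assert summer_p90(a * x + b) == pytest.approx(a * summer_p90(x) + b, rel=1e-9)


def test_multi_year_p90_averages_per_summer_percentiles():
    s = make_series({2020: 90.0, 2021: 94.0}, tmax_by_year={2020: 90.0, 2021: 94.0})
    assert multi_year_p90(s, (2020, 2021)) == 92.0
    s2 = make_series({2020: 91.0, 2021: 91.0}, tmax_by_year={2020: 91.0, 2021: 91.0})
    assert multi_year_p90(s2, (2020, 2021)) == summer_p90(np.full(92, 91.0))


def test_anomaly_zero_for_identical_summers():
    s = make_series({y: 88.0 for y in range(1990, 2024)})
    assert p90_anomaly(s, (2020, 2023), (1990, 2019)) == 0.0


def test_anomaly_tracks_uniform_shift_exactly():
    vals = {y: np.linspace(80, 95, 92) for y in range(1990, 2024)}
    for y in range(2020, 2024):
        vals[y] = vals[y] + 2.0
    s = make_series(vals, tmax_by_year=vals)
    assert p90_anomaly(s, (2020, 2023), (1990, 2019)) == pytest.approx(2.0)


def test_overlapping_year_ranges_rejected():
    s = make_series({y: 88.0 for y in range(2018, 2024)})
    with pytest.raises(ValueError, match="overlap"):
        p90_anomaly(s, (2020, 2023), (2018, 2020))
    with pytest.raises(ValueError, match="overlap"):
        risk_days(s, (2020, 2023), (2018, 2021))


def test_risk_days_zero_for_constant_series():
    s = make_series({y: 85.0 for y in range(1990, 2024)})
    assert risk_days(s, (2020, 2023), (1990, 2019)) == 0


def test_risk_days_counts_constructed_exceedances():
    vals = {y: np.full(92, 80.0) for y in range(1990, 2024)}
    vals[2022][10:14] = 91.0  # exactly 4 days > 80 + 10
    vals[2023][50] = 90.0  # boundary day, excluded by strict inequality
    s = make_series(vals)
    assert risk_days(s, (2020, 2023), (1990, 2019)) == 4


def test_risk_days_matches_enumeration_oracle():
    rng = np.random.default_rng(8)
    vals = {y: rng.normal(82, 5, 92) for y in range(1990, 2024)}
    s = make_series(vals)
    base = np.mean([vals[y] for y in range(1990, 2020)])
    manual = sum(
        1 for y in range(2020, 2024) for v in vals[y] if v > base + 10.0
    )
    assert risk_days(s, (2020, 2023), (1990, 2019)) == manual


def test_metrics_invariant_to_facility_order_and_monotone():
    rng = np.random.default_rng(10)
    vals = {y: rng.normal(84, 4, 92) for y in range(1990, 2024)}
    s = make_series(vals)
    rec = compute_metrics(s, (2020, 2023), (1990, 2019))
    # raise one analysis-period day: all exceedance metrics non-decreasing
    vals2 = {y: v.copy() for y, v in vals.items()}
    vals2[2021][7] += 30.0
    rec2 = compute_metrics(make_series(vals2), (2020, 2023), (1990, 2019))
    assert rec2.days_above_85 >= rec.days_above_85
    assert rec2.p90_tmax >= rec.p90_tmax
    assert rec2.anomaly >= rec.anomaly
    # risk-day baseline unchanged (analysis-period bump only)
    assert rec2.risk_days >= rec.risk_days


def test_celsius_pipeline_commutes_with_fahrenheit_pipeline(flat_config):
    """Running on a degC grid with conversion equals a pre-converted grid."""
    from dataclasses import replace

    from prisonheat.climate import filter_summer, to_fahrenheit
    from prisonheat.synthetic import generate_climate
    from prisonheat.zonal import cell_weights, extract_daily_series

    cfg = replace(flat_config, noise_sd=1.0, trend=0.3, seed=2)
    grid_f = generate_climate(cfg)
    grid_c = replace(
        grid_f,
        tmax=(grid_f.tmax - 32.0) * 5.0 / 9.0,
        tmin=(grid_f.tmin - 32.0) * 5.0 / 9.0,
        units="degC",
    )
    from shapely.geometry import box

    geom = box(grid_f.x[0], grid_f.y[0], grid_f.x[2], grid_f.y[2])
    recs = []
    for g in (grid_f, to_fahrenheit(grid_c)):
        summer = filter_summer(g)
        s = extract_daily_series(summer, cell_weights(geom, summer, "F0"))
        recs.append(compute_metrics(s, (2002, 2003), (2000, 2001)))
    assert recs[0].p90_tmax == pytest.approx(recs[1].p90_tmax, abs=1e-9)
    assert recs[0].days_above_85 == recs[1].days_above_85
    assert recs[0].risk_days == recs[1].risk_days


def test_state_summary_mean_and_sample_sd():
    m = metrics_table(
        [
            compute_metrics(make_series({y: t for y in range(1990, 2024)},
                                        tmax_by_year={y: t for y in range(1990, 2024)}),
                            (2020, 2023), (1990, 2019))
            for t in (90.0, 94.0)
        ]
    )
    m.index = ["A", "B"]
    states = pd.Series({"A": "TX", "B": "TX"})
    out = state_summary(m, states)
    assert out.loc["TX", "mean_p90"] == 92.0
    assert out.loc["TX", "sd_p90"] == pytest.approx(np.sqrt(8.0))  # 2.828...


def test_single_facility_state_has_undefined_sd():
    rec = compute_metrics(
        make_series({y: 90.0 for y in range(1990, 2024)}), (2020, 2023), (1990, 2019)
    )
    m = metrics_table([rec])
    out = state_summary(m, pd.Series({rec.facility_id: "WY"}))
    assert out.loc["WY", "n_facilities"] == 1
    assert np.isnan(out.loc["WY", "sd_p90"])


def test_state_summary_order_invariant():
    recs = [
        compute_metrics(
            make_series({y: t for y in range(1990, 2024)}, fid=f"F{i}"),
            (2020, 2023),
            (1990, 2019),
        )
        for i, t in enumerate((88.0, 91.0, 95.0))
    ]
    states = pd.Series({"F0": "TX", "F1": "CA", "F2": "TX"})
    a = state_summary(metrics_table(recs), states)
    b = state_summary(metrics_table(recs[::-1]), states)
    pd.testing.assert_frame_equal(a, b)


def test_exceedance_share_counts_and_errors():
    recs = []
    for i, t in enumerate((90.0, 80.0, 80.0, 86.0)):
        recs.append(
            compute_metrics(
                make_series({y: t for y in range(1990, 2024)}, fid=f"F{i}"),
                (2020, 2023),
                (1990, 2019),
            )
        )
    m = metrics_table(recs)
    cnt, frac = exceedance_share(m, "any_day_above_threshold")
    assert (cnt, frac) == (2, 0.5)
    cnt, frac = exceedance_share(m, "all")
    assert (cnt, frac) == (4, 1.0)
    with pytest.raises(ValueError, match="unknown exceedance predicate"):
        exceedance_share(m, "nope")
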