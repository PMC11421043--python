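"""Compute the four summer heat metrics for one facility.

Builds a tiny one-facility scene in memory: a flat 80 degF climate with a
five-day +15 degF heatwave in 2021, so each metric's value is predictable
from the construction.
"""

from shapely.geometry import box

from prisonheat import (
    ClimateSimConfig,
    compute_metrics,
    cell_weights,
    extract_daily_series,
    filter_summer,
    generate_climate,
)

cfg = ClimateSimConfig(
    grid_ny=2,
    grid_nx=2,
    years=(1990, 2023),
    base_field=80.0,
    seasonal_amplitude=0.0,
    diurnal_range=0.0,
    trend=0.0,
    noise_sd=0.0,
    heatwave_events=[(2021, 10, 5, 15.0)],  # 5 days at 95 degF
)
summer = filter_summer(generate_climate(cfg))

facility = box(-500, -500, 500, 500)  # one grid cell
weights = cell_weights(facility, summer, "EXAMPLE")
series = extract_daily_series(summer, weights)
rec = compute_metrics(series, analysis_years=(2020, 2023), baseline_years=(1990, 2019))

print(f"days above 85 degF (mean per summer): {rec.days_above_85}")   # 1.25 = 5/4
print(f"p90 of daily tmax (degF):             {rec.p90_tmax}")
print(f"anomaly vs 1990-2019 baseline (degF): {rec.anomaly}")
print(f"risk days (>10 degF above local mean): {rec.risk_days}")       # exactly 5
# The 5 heatwave days are the only exceedances: they exceed both the 85 degF
# policy threshold and the local-mean + 10 degF mortality-risk threshold.
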