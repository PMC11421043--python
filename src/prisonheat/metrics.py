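"""The four facility-level summer heat metrics and their summaries.

Per facility, over a summer-filtered daily series in °F:

(a) ``mean_annual_days_above`` — mean number of summer days per year with
    daily mean temperature strictly above a threshold (default 85 °F, a
    common upper limit in carceral thermoregulation policies);
(b) ``summer_p90`` / ``multi_year_p90`` — the 90th percentile of daily
    maximum temperature, per summer, averaged over the analysis years;
(c) ``p90_anomaly`` — analysis-period average p90 minus a multi-decade
    baseline average p90 at the same location (warming signal);
(d) ``risk_days`` — count of analysis-period days whose daily mean exceeds
    the location-specific baseline mean summer temperature by more than a
    fixed offset (default 10 °F). In the epidemiological literature each such
    day is associated with a 5.2% increase in total mortality in prison
    populations; that constant is carried as metadata, never computed here.

Conventions (fixed and recorded in output provenance): strict ``>`` for both
threshold metrics; percentiles by linear interpolation between order
statistics (sorted rank position 1 + 0.9·(n−1)); per-summer percentile then
averaged across years rather than a pooled percentile; sample SD (n−1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zonal import FacilityDailySeries

__all__ = [
    "RISK_DAY_MORTALITY_INCREASE",
    "HeatMetricsRecord",
    "StateSummary",
    "mean_annual_days_above",
    "summer_p90",
    "multi_year_p90",
    "p90_anomaly",
    "risk_days",
    "compute_metrics",
    "metrics_table",
    "state_summary",
    "exceedance_share",
    "EXCEEDANCE_PREDICATES",
]

#: Literature-derived interpretation of one risk day (fractional increase in
#: total mortality). Metadata only — attached to outputs, never computed.
RISK_DAY_MORTALITY_INCREASE = 0.052


@dataclass
class HeatMetricsRecord:
    """The four heat metrics for one facility."""

    facility_id: str
    days_above_85: float  # mean days per summer, analysis years
    any_day_above_85: bool  # >=1 exceedance day in any analysis year
    p90_tmax: float  # °F, analysis-year average of per-summer p90
    anomaly: float  # °F, analysis minus baseline average p90
    risk_days: int  # total over analysis years
    analysis_years: tuple
    baseline_years: tuple
    threshold_f: float = 85.0
    risk_offset_f: float = 10.0
    metadata: dict = field(default_factory=dict)


@dataclass
class StateSummary:
    state: str
    n_facilities: int
    mean_p90: float
    sd_p90: float  # NaN when n == 1 (sample SD undefined)


def _years_range(years) -> np.ndarray:
    y0, y1 = int(years[0]), int(years[-1])
    if y1 < y0:
        raise ValueError("year range reversed")
    return np.arange(y0, y1 + 1)


def _yearly(series: FacilityDailySeries, years, attr: str):
    """Yield (year, values) over the requested years; error on a missing summer."""
    have = series.dates[:, 0]
    for y in _years_range(years):
        mask = have == y
        if not mask.any():
            raise ValueError(f"facility {series.facility_id!r}: no data for summer {y}")
        yield int(y), getattr(series, attr)[mask]


def mean_annual_days_above(
    series: FacilityDailySeries, threshold: float, years
) -> tuple[float, bool]:
    """Mean days per summer with daily mean strictly above ``threshold``.

    Returns ``(mean_days, any_exceedance)`` where the flag is True when at
    least one day in any requested year exceeds the threshold.
    """
    counts = [int(np.sum(v > threshold)) for _, v in _yearly(series, years, "tmean_f")]
    return float(np.mean(counts)), any(c > 0 for c in counts)


def summer_p90(values) -> float:
    """90th percentile by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input to summer_p90")
    return float(np.quantile(values, 0.9, method="linear"))


def multi_year_p90(series: FacilityDailySeries, years, pooled: bool = False) -> float:
    """Average of per-summer p90 of daily tmax (default), or pooled percentile.

    The per-year-then-average convention is the primary definition; ``pooled``
    computes a single percentile over all days of the range instead and is
    labelled as such in pipeline provenance.
    """
    if pooled:
        vals = np.concatenate([v for _, v in _yearly(series, years, "tmax_f")])
        return summer_p90(vals)
    return float(np.mean([summer_p90(v) for _, v in _yearly(series, years, "tmax_f")]))


def p90_anomaly(
    series: FacilityDailySeries, analysis_years, baseline_years, pooled: bool = False
) -> float:
    """Analysis-period average p90 minus baseline-period average p90 (°F)."""
    a = set(_years_range(analysis_years).tolist())
    b = set(_years_range(baseline_years).tolist())
    if a & b:
        raise ValueError("analysis and baseline year ranges overlap")
    return multi_year_p90(series, analysis_years, pooled) - multi_year_p90(
        series, baseline_years, pooled
    )


def risk_days(
    series: FacilityDailySeries,
    analysis_years,
    baseline_years,
    offset: float = 10.0,
    variable: str = "tmean",
) -> int:
    """Days in the analysis period more than ``offset`` °F above the baseline
    location-specific mean summer temperature.

    The baseline is the mean of daily ``variable`` (default tmean; a tmax
    variant is available) over all baseline summers; counting uses a strict
    inequality.
    """
    a = set(_years_range(analysis_years).tolist())
    b = set(_years_range(baseline_years).tolist())
    if a & b:
        raise ValueError("analysis and baseline year ranges overlap")
    attr = {"tmean": "tmean_f", "tmax": "tmax_f"}.get(variable)
    if attr is None:
        raise ValueError(f"unknown risk-day variable: {variable!r}")
    base_vals = np.concatenate([v for _, v in _yearly(series, baseline_years, attr)])
    if base_vals.size == 0:
        raise ValueError("empty baseline for risk_days")
    base = float(np.mean(base_vals))
    total = 0
    for _, v in _yearly(series, analysis_years, attr):
        total += int(np.sum(v > base + offset))
    return total


def compute_metrics(
    series: FacilityDailySeries,
    analysis_years=(2020, 2023),
    baseline_years=(1990, 2019),
    threshold: float = 85.0,
    risk_offset: float = 10.0,
    pooled_percentile: bool = False,
    risk_variable: str = "tmean",
) -> HeatMetricsRecord:
    """All four metrics for one facility series."""
    mean_days, any_day = mean_annual_days_above(series, threshold, analysis_years)
    return HeatMetricsRecord(
        facility_id=series.facility_id,
        days_above_85=mean_days,
        any_day_above_85=any_day,
        p90_tmax=multi_year_p90(series, analysis_years, pooled_percentile),
        anomaly=p90_anomaly(series, analysis_years, baseline_years, pooled_percentile),
        risk_days=risk_days(
            series, analysis_years, baseline_years, risk_offset, risk_variable
        ),
        analysis_years=tuple(analysis_years),
        baseline_years=tuple(baseline_years),
        threshold_f=threshold,
        risk_offset_f=risk_offset,
        metadata={
            "risk_day_mortality_increase": RISK_DAY_MORTALITY_INCREASE,
            "percentile_rule": "linear order-statistic interpolation",
            "percentile_pooling": "pooled" if pooled_percentile else "per-year mean",
            "risk_variable": risk_variable,
        },
    )


def metrics_table(records) -> pd.DataFrame:
    """One row per facility; index facility_id."""
    rows = [
        {
            "facility_id": r.facility_id,
            "days_above_85": r.days_above_85,
            "any_day_above_85": r.any_day_above_85,
            "p90_tmax": r.p90_tmax,
            "anomaly": r.anomaly,
            "risk_days": r.risk_days,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("facility_id")


def state_summary(metrics: pd.DataFrame, states: pd.Series) -> pd.DataFrame:
    """Unweighted per-state mean and sample SD (n−1) of facility p90.

    ``states`` maps facility_id -> two-letter state code; every facility in
    the metrics table must be mapped. SD is NaN for single-facility states.
    """
    missing = metrics.index.difference(states.index)
    if len(missing):
        raise ValueError(f"facilities without a state: {list(missing)[:5]}")
    df = metrics.join(states.rename("state"))
    g = df.groupby("state")["p90_tmax"]
    out = pd.DataFrame(
        {"n_facilities": g.size(), "mean_p90": g.mean(), "sd_p90": g.std(ddof=1)}
    )
    return out.sort_index()


#: Named cohort-level predicates over the metrics table.
EXCEEDANCE_PREDICATES = {
    "any_day_above_threshold": lambda df: df["any_day_above_85"].astype(bool),
    "any_risk_day": lambda df: df["risk_days"] >= 1,
    "positive_anomaly": lambda df: df["anomaly"] > 0,
    "all": lambda df: pd.Series(True, index=df.index),
}


def exceedance_share(metrics: pd.DataFrame, predicate: str) -> tuple[int, float]:
    """Count and fraction of facilities satisfying a named predicate."""
    try:
        fn = EXCEEDANCE_PREDICATES[predicate]
    except KeyError:
        raise ValueError(f"unknown exceedance predicate: {predicate!r}") from None
    flags = fn(metrics)
    return int(flags.sum()), float(flags.mean())
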