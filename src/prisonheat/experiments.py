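"""Calibration and recovery experiments used by the validation suite.

These run the package's own machinery against the synthetic generator's
closed-form expectations: trend recovery through the anomaly metric, power to
detect a planted exposure gap across a binary characteristic, and the type-I
error of the full test-selection battery under the null. They are ordinary
library functions so validation and reporting share one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import filter_summer
from .facilities import CHARACTERISTIC_KINDS, CENSUS_CATEGORIES
from .metrics import compute_metrics
from .risk_tests import TestPolicy, compare_binary, run_battery
from .synthetic import (
    ClimateSimConfig,
    CohortSimConfig,
    generate_climate,
    generate_facilities,
)
from .zonal import cell_weights, extract_daily_series

__all__ = [
    "anomaly_recovery",
    "planted_effect_power",
    "null_battery_type1",
    "make_accounting_cohort",
]

#: Between-facility spread of summer p90 exposure within one synthetic region
#: (°F); the scale of local climatological variation the cohort generator
#: emulates inside a region.
WITHIN_REGION_EXPOSURE_SD = 2.0


def anomaly_recovery(
    trend: float,
    n_facilities: int = 120,
    grid_ny: int = 12,
    grid_nx: int = 12,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> dict:
    """Estimate the mean anomaly over many synthetic facilities vs its
    closed-form expectation trend × (mean(2020–2023) − mean(1990–2019)) = 17·trend.

    One facility per grid cell (cycling) with a one-cell rectangular
    footprint; facilities in distinct cells see independent daily noise, so
    the standard error of the mean anomaly shrinks as 1/√n_facilities.
    """
    rng = np.random.default_rng(seed)
    base = 78.0 + rng.normal(0.0, 2.0, size=(grid_ny, grid_nx))
    cfg = ClimateSimConfig(
        grid_ny=grid_ny,
        grid_nx=grid_nx,
        years=(1990, 2023),
        base_field=base,
        trend=trend,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    grid = filter_summer(generate_climate(cfg))
    dy, dx = grid.spacing()
    anomalies = []
    cells = [(r, c) for r in range(grid_ny) for c in range(grid_nx)]
    for i in range(n_facilities):
        r, c = cells[i % len(cells)]
        from shapely.geometry import box

        geom = box(
            grid.x[c] - dx / 2, grid.y[r] - dy / 2, grid.x[c] + dx / 2, grid.y[r] + dy / 2
        )
        w = cell_weights(geom, grid, f"F{i:04d}")
        s = extract_daily_series(grid, w)
        rec = compute_metrics(s, (2020, 2023), (1990, 2019))
        anomalies.append(rec.anomaly)
    anomalies = np.asarray(anomalies)
    n_indep = min(n_facilities, grid_ny * grid_nx)
    return {
        "trend": trend,
        "expected_anomaly": 17.0 * trend,
        "mean_anomaly": float(anomalies.mean()),
        "se": float(anomalies[:n_indep].std(ddof=1) / np.sqrt(n_indep)),
        "n_facilities": n_facilities,
    }


def planted_effect_power(
    delta: float = 2.0,
    n_per_group: int = 100,
    n_reps: int = 200,
    sd: float = WITHIN_REGION_EXPOSURE_SD,
    policy: TestPolicy = TestPolicy(),
    seed: int = 0,
) -> dict:
    """Fraction of replicates recovering a planted exposure gap as significant
    with the correct (positive) sign.

    Exposures are drawn at the facility level from the generator's
    within-region model: normal with SD ``sd`` around region means ``delta``
    apart, mirroring a binary characteristic that places facilities in the
    hot region.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        hot = rng.normal(delta, sd, n_per_group)
        cool = rng.normal(0.0, sd, n_per_group)
        res = compare_binary("planted", {"yes": hot, "no": cool}, policy)
        if res.significant and res.difference > 0:
            hits += 1
    return {
        "delta_f": delta,
        "n_per_group": n_per_group,
        "n_reps": n_reps,
        "power": hits / n_reps,
    }


def _null_cohort_attributes(n: int, rng) -> pd.DataFrame:
    """Attribute table with the 17 characteristics drawn independently of
    exposure, at moderate prevalences so groups are testable at modest n."""
    data = {}
    for var, kind in CHARACTERISTIC_KINDS.items():
        if kind == "binary":
            data[var] = np.where(rng.random(n) < 0.3, "yes", "no")
        else:
            levels = list(kind)
            data[var] = rng.choice(levels, size=n)
    return pd.DataFrame(data)


def null_battery_type1(
    n_facilities: int = 200,
    n_reps: int = 1000,
    policy: TestPolicy = TestPolicy(),
    seed: int = 0,
) -> dict:
    """Type-I error of the full selection-then-test battery under the null.

    Each replicate draws facility exposures independent of every
    characteristic and runs the 17-variable battery; the rate is the share of
    testable comparisons declared significant. Selection between t and
    Wilcoxon (and ANOVA vs Welch) makes the procedure only approximately
    α-level, so the measured rate is reported rather than assumed.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_tests = 0
    for _ in range(n_reps):
        df = _null_cohort_attributes(n_facilities, rng)
        df["p90_tmax"] = rng.normal(93.0, 4.5, n_facilities)
        for res in run_battery(df, exposure_col="p90_tmax", policy=policy):
            if res.test_used == "untestable":
                continue
            n_tests += 1
            n_sig += int(res.significant)
    return {
        "n_reps": n_reps,
        "n_tests": n_tests,
        "type1_rate": n_sig / n_tests,
        "alpha": policy.alpha,
    }


def make_accounting_cohort(
    n_total: int = 1614,
    n_akhi: int = 20,
    n_unmatched: int = 322,
    n_incomplete: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """A cohort table with prescribed accounting structure, for exercising the
    join/filter bookkeeping at realistic scale without geometry.

    ``n_unmatched`` records carry no attribute row at all (so their
    demographics are also missing); ``n_incomplete`` matched records are
    missing one race/ethnicity count. The three exclusion sets are disjoint.
    """
    if n_akhi + n_incomplete + n_unmatched > n_total:
        raise ValueError("overlapping accounting sets not supported")
    rng = np.random.default_rng(seed)
    ids = [f"F{i:04d}" for i in range(n_total)]
    states = np.array(["TX"] * n_total, dtype=object)
    states[:n_akhi] = rng.choice(["AK", "HI"], size=n_akhi)
    df = pd.DataFrame({"facility_id": ids, "state": states}).set_index(
        "facility_id", drop=False
    )
    df["attributes_missing"] = False
    unmatched = slice(n_akhi, n_akhi + n_unmatched)
    df.iloc[unmatched, df.columns.get_loc("attributes_missing")] = True
    for cat in CENSUS_CATEGORIES:
        df[cat] = 10.0
        df.iloc[unmatched, df.columns.get_loc(cat)] = np.nan
    lo = n_akhi + n_unmatched
    df.iloc[lo : lo + n_incomplete, df.columns.get_loc(CENSUS_CATEGORIES[0])] = np.nan
    return df
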