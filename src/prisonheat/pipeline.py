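"""End-to-end orchestration from a single declarative config.

Stages run in a fixed order — read climate, convert to °F, summer filter,
read and filter facilities, zonal extraction, heat metrics, state and
exceedance summaries, equity tables, risk-factor test battery — and every
defaulted methodological decision (percentile rule, strict thresholds, zonal
mode, year ranges) is written into a machine-readable provenance record so a
rerun with the same inputs is reproducible. A stage failure aborts with the
stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import SUMMER_WINDOW, filter_summer, read_climate_grid, to_fahrenheit
from .equity import compare_extremes, weighted_exposure_table
from .facilities import apply_cohort_filters, read_facilities, recode_demographics
from .metrics import compute_metrics, exceedance_share, metrics_table, state_summary
from .risk_tests import TestPolicy, battery_frame, run_battery
from .zonal import cell_weights, extract_daily_series

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("prisonheat")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    climate_paths: list
    facility_vector: str
    facility_attributes: str
    output_dir: str
    key: str = "facility_id"
    variables: dict = field(default_factory=dict)  # e.g. {"tmax": "tasmax"}
    summer_window: tuple = SUMMER_WINDOW
    analysis_years: tuple = (2020, 2023)
    baseline_years: tuple = (1990, 2019)
    threshold_f: float = 85.0
    risk_offset_f: float = 10.0
    pooled_percentile: bool = False
    risk_variable: str = "tmean"
    zonal_mode: str = "area"
    cohort_filters: list = field(
        default_factory=lambda: [
            "exclude-states",
            "require-attributes",
            "require-complete-demographics",
        ]
    )
    equity_k: int = 10
    equity_decile: bool = True
    proportion_mode: str = "pooled"
    equity_years: tuple | None = None  # exposure years for equity/tests; None -> analysis
    policy: TestPolicy = field(default_factory=TestPolicy)
    seed: int = 0

    def __post_init__(self):
        a = set(range(self.analysis_years[0], self.analysis_years[-1] + 1))
        b = set(range(self.baseline_years[0], self.baseline_years[-1] + 1))
        if a & b:
            raise ValueError("analysis and baseline year ranges overlap")
        for v in (self.threshold_f, self.risk_offset_f):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "policy" in raw and isinstance(raw["policy"], dict):
            raw["policy"] = TestPolicy(**raw["policy"])
        for k in ("summer_window", "analysis_years", "baseline_years", "equity_years"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[k]) \
                    if k == "summer_window" else tuple(raw[k])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["climate_paths"] = [str(p) for p in d["climate_paths"]]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    state_summary: pd.DataFrame
    exceedance: pd.DataFrame
    weighted_exposure: pd.DataFrame
    extreme_comparison: object
    battery: pd.DataFrame
    filter_log: pd.DataFrame
    provenance: dict
    output_dir: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as e:
                raise PipelineStageError(name, str(e)) from e

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all output tables under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid = _stage("climate_io")(
        lambda: to_fahrenheit(read_climate_grid(config.climate_paths, config.variables))
    )()
    summer = _stage("climate_io")(lambda: filter_summer(grid, config.summer_window))()
    log.info("climate: %d summer days on %dx%d grid", summer.n_time, summer.y.size, summer.x.size)

    records, flog = _stage("facility_io")(
        lambda: read_facilities(
            config.facility_vector, config.facility_attributes, config.key
        )
    )()
    cohort, flog = _stage("facility_io")(
        lambda: apply_cohort_filters(records, config.cohort_filters, flog)
    )()
    log.info("cohort: %d facilities after filters", len(cohort))

    @_stage("zonal_extraction")
    def _extract():
        series = {}
        for fid, row in records.iterrows():
            w = cell_weights(row["geometry"], summer, fid, mode=config.zonal_mode)
            series[fid] = extract_daily_series(summer, w)
        return series

    series = _extract()

    @_stage("heat_metrics")
    def _metrics():
        recs = [
            compute_metrics(
                s,
                config.analysis_years,
                config.baseline_years,
                config.threshold_f,
                config.risk_offset_f,
                config.pooled_percentile,
                config.risk_variable,
            )
            for s in series.values()
        ]
        return metrics_table(recs)

    mtable = _metrics()
    states = records["state"]
    ssum = _stage("heat_metrics")(lambda: state_summary(mtable, states))()
    shares = []
    for pred in ("any_day_above_threshold", "any_risk_day", "positive_anomaly"):
        cnt, frac = exceedance_share(mtable, pred)
        shares.append({"predicate": pred, "count": cnt, "fraction": frac})
    exc = pd.DataFrame(shares).set_index("predicate")

    @_stage("equity_analysis")
    def _equity():
        from .metrics import multi_year_p90

        profiles = recode_demographics(cohort)
        if config.equity_years is not None:
            expo = pd.Series(
                {
                    fid: multi_year_p90(series[fid], config.equity_years)
                    for fid in cohort.index
                }
            )
        else:
            expo = mtable.loc[cohort.index, "p90_tmax"]
        wtable = weighted_exposure_table(
            expo, profiles.loc[profiles["complete"], ["white_nh", "black_nh", "hispanic", "nonwhite_nh"]]
        )
        comp = compare_extremes(
            expo,
            profiles,
            k=None if config.equity_decile else config.equity_k,
            decile=config.equity_decile,
            mode=config.proportion_mode,
        )
        return expo, wtable, comp

    expo, wtable, comp = _equity()

    @_stage("risk_factor_tests")
    def _tests():
        data = cohort.copy()
        data["exposure"] = expo
        return battery_frame(
            run_battery(data, exposure_col="exposure", policy=config.policy)
        )

    battery = _tests()

    provenance = {
        "software": f"prisonheat {__version__}",
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "decisions": {
            "daily_mean": "(tmax + tmin) / 2",
            "thresholds": "strict > for days-above and risk days",
            "percentile": "linear order-statistic interpolation, "
            + ("pooled across years" if config.pooled_percentile else "per-year then averaged"),
            "zonal_mode": config.zonal_mode,
            "risk_variable": config.risk_variable,
            "multiple_testing": "none across battery (BH column is a labelled extension)",
        },
    }

    # ---- write the bundle -------------------------------------------------
    header = "# " + json.dumps(provenance["decisions"]) + "\n"
    with open(out / "facility_metrics.csv", "w") as fh:
        fh.write(header)
        mtable.to_csv(fh)
    ssum.to_csv(out / "state_summary.csv")
    exc.to_csv(out / "exceedance.csv")
    wtable.to_csv(out / "equity_weighted_exposure.csv")
    pd.DataFrame(
        {
            "hot": comp.hot_proportions,
            "cool": comp.cool_proportions,
            "difference_pp": comp.differences_pp,
        }
    ).to_csv(out / "equity_proportion_differences.csv")
    pd.DataFrame(
        {"facility_id": comp.hot_ids + comp.cool_ids,
         "set": ["hot"] * len(comp.hot_ids) + ["cool"] * len(comp.cool_ids)}
    ).to_csv(out / "extreme_sets.csv", index=False)
    battery.to_csv(out / "risk_factor_battery.csv")
    flog.as_frame().to_csv(out / "filter_log.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    return PipelineResult(
        metrics=mtable,
        state_summary=ssum,
        exceedance=exc,
        weighted_exposure=wtable,
        extreme_comparison=comp,
        battery=battery,
        filter_log=flog.as_frame(),
        provenance=provenance,
        output_dir=out,
    )
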