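"""Demographic equity in heat exposure.

Three views of how exposure is distributed across incarcerated demographic
groups:

- population-weighted exposure per group g:
      T_g = Σ_i T_i · p_{i,g} / Σ_i p_{i,g}
  over facilities i with complete data, where T_i is the facility exposure
  (typically the summer p90 of daily tmax) and p_{i,g} the group population;
- top-k / bottom-k (or top/bottom decile) facility sets by exposure, with
  deterministic tie-breaking;
- pooled demographic composition of those extreme sets and the hot − cool
  differences in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupExposure",
    "ExtremeSets",
    "ExtremeSetComparison",
    "decile_count",
    "population_weighted_exposure",
    "rank_extremes",
    "group_proportions",
    "compare_extremes",
]

#: Demographic groups reported; the first three partition the population
#: (nonwhite_nh includes black_nh, which is also reported on its own).
PARTITION_GROUPS = ("white_nh", "hispanic", "nonwhite_nh")
REPORT_GROUPS = ("white_nh", "black_nh", "hispanic", "nonwhite_nh")


@dataclass
class GroupExposure:
    group: str
    weighted_exposure: float  # °F
    total_population: float
    n_facilities: int


@dataclass
class ExtremeSets:
    k: int
    hot_ids: list
    cool_ids: list


@dataclass
class ExtremeSetComparison:
    k: int
    hot_ids: list
    cool_ids: list
    hot_proportions: pd.Series
    cool_proportions: pd.Series
    differences_pp: pd.Series  # hot − cool, percentage points
    mode: str = "pooled"


def decile_count(n: int) -> int:
    """Size of one decile of an n-element cohort: floor(n / 10)."""
    return int(n) // 10


def population_weighted_exposure(
    exposures: pd.Series, populations: pd.DataFrame
) -> dict[str, GroupExposure]:
    """Population-weighted mean exposure per demographic group.

    Parameters
    ----------
    exposures : facility_id -> exposure (°F). NaN exposures are excluded.
    populations : facility_id × group population counts; NaN counts exclude a
        facility from that group's sum only. Zero-population facilities carry
        zero weight and drop out naturally.

    Raises
    ------
    ValueError if a group has zero total population among usable facilities.
    """
    exposures = exposures.dropna()
    out = {}
    for group in populations.columns:
        p = populations[group].reindex(exposures.index).dropna()
        t = exposures.reindex(p.index)
        total = float(p.sum())
        if total <= 0:
            raise ValueError(f"zero total population for group {group!r}")
        out[group] = GroupExposure(
            group=group,
            weighted_exposure=float((t * p).sum() / total),
            total_population=total,
            n_facilities=int((p > 0).sum()),
        )
    return out


def weighted_exposure_table(exposures, populations) -> pd.DataFrame:
    res = population_weighted_exposure(exposures, populations)
    return pd.DataFrame(
        [
            {
                "group": g.group,
                "weighted_exposure_f": g.weighted_exposure,
                "total_population": g.total_population,
                "n_facilities": g.n_facilities,
            }
            for g in res.values()
        ]
    ).set_index("group")


def rank_extremes(
    exposures: pd.Series, k: int | None = None, decile: bool = False
) -> ExtremeSets:
    """Top-k (hot) and bottom-k (cool) facility sets by exposure.

    Boundary ties are broken by ascending facility id so output is a pure
    function of the data. ``decile=True`` uses k = floor(N / 10).
    """
    exposures = exposures.dropna()
    n = len(exposures)
    if decile:
        k = decile_count(n)
    if k is None:
        raise ValueError("either k or decile=True must be given")
    if k < 1 or n < 2 * k:
        raise ValueError(f"cohort of {n} too small for two disjoint sets of {k}")
    df = pd.DataFrame({"t": exposures}).reset_index()
    df.columns = ["facility_id", "t"]
    # one ascending sort keyed on (exposure, id) keeps the two sets disjoint
    # even when ties span a set boundary
    asc = df.sort_values(["t", "facility_id"], ascending=[True, True])
    cool = asc.head(k)["facility_id"].tolist()
    hot = asc.tail(k)["facility_id"].tolist()[::-1]  # hottest first
    return ExtremeSets(k=k, hot_ids=hot, cool_ids=cool)


def group_proportions(
    ids, profiles: pd.DataFrame, mode: str = "pooled"
) -> pd.Series:
    """Demographic composition of a facility set.

    ``pooled`` (default): Σ group count / Σ total count over the set, i.e.
    the composition of the aggregate population. ``facility_mean``: mean of
    per-facility shares, weighting facilities equally. Every facility in the
    set must have a complete profile.
    """
    sub = profiles.loc[list(ids)]
    if "complete" in sub.columns and not sub["complete"].all():
        bad = sub.index[~sub["complete"]].tolist()
        raise ValueError(f"incomplete demographic profile in set: {bad[:5]}")
    groups = [g for g in REPORT_GROUPS if g in sub.columns]
    if mode == "pooled":
        total = sub["total"].sum()
        if total <= 0:
            raise ValueError("zero aggregate population in set")
        return pd.Series({g: float(sub[g].sum() / total) for g in groups})
    if mode == "facility_mean":
        shares = sub[groups].div(sub["total"], axis=0)
        return shares.mean()
    raise ValueError(f"unknown proportion mode: {mode!r}")


def compare_extremes(
    exposures: pd.Series,
    profiles: pd.DataFrame,
    k: int | None = None,
    decile: bool = False,
    mode: str = "pooled",
) -> ExtremeSetComparison:
    """Demographic composition of the hottest vs coolest facility sets."""
    sets = rank_extremes(exposures, k=k, decile=decile)
    hot = group_proportions(sets.hot_ids, profiles, mode)
    cool = group_proportions(sets.cool_ids, profiles, mode)
    return ExtremeSetComparison(
        k=sets.k,
        hot_ids=sets.hot_ids,
        cool_ids=sets.cool_ids,
        hot_proportions=hot,
        cool_proportions=cool,
        differences_pp=(hot - cool) * 100.0,
        mode=mode,
    )
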