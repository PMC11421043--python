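"""Facility cohort handling: vector + attribute join, filters, demographics.

The cohort table carries one row per facility with a shapely geometry column,
the eight census race/ethnicity population counts, and the seventeen
facility-level characteristics hypothesized to modify heat risk (fourteen
binary court-order / function / labor variables plus security level, the
share of the population permitted to leave, and the operator).

Joining is exact on a shared key — probabilistic record linkage between the
boundary and census sources is out of scope here and must be resolved
upstream. Filters reproduce the cohort construction used in facility heat
studies: drop Alaska/Hawaii, drop records without attributes, drop records
with incomplete race/ethnicity data. Every stage is logged so the accounting
reconciles exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape

__all__ = [
    "CENSUS_CATEGORIES",
    "NONWHITE_NH_COMPONENTS",
    "CHARACTERISTIC_KINDS",
    "CHARACTERISTIC_RISK_LEVELS",
    "FilterStage",
    "FilterLog",
    "read_facilities",
    "apply_cohort_filters",
    "recode_demographics",
]

#: The eight census race/ethnicity categories (population counts per facility).
CENSUS_CATEGORIES = (
    "white_nh",
    "black_nh",
    "hispanic",
    "aian_nh",
    "asian_nh",
    "nhpi_nh",
    "two_or_more_nh",
    "additional_nh",
)

#: The six categories pooled into the non-white, non-Hispanic group (all
#: categories except white NH and Hispanic; "additional categories" counts
#: as non-white, non-Hispanic).
NONWHITE_NH_COMPONENTS = tuple(
    c for c in CENSUS_CATEGORIES if c not in ("white_nh", "hispanic")
)

#: The 17 facility-level heat-risk characteristics: 14 binary plus 3 categorical.
CHARACTERISTIC_KINDS = {
    "geriatric_unit": "binary",
    "poor_crowding": "binary",
    "poor_mental_health": "binary",
    "poor_medical": "binary",
    "poor_disability_accommodations": "binary",
    "poor_disciplinary": "binary",
    "poor_grievance": "binary",
    "poor_staffing": "binary",
    "poor_totality": "binary",
    "work_agriculture": "binary",
    "function_medical": "binary",
    "function_mental_health": "binary",
    "function_geriatric": "binary",
    "function_boot_camp": "binary",
    "security_level": ("minimum/low", "medium", "maximum/high"),
    "percent_leave": ("50% or more", "less than 50%", "none"),
    "operator": ("public", "private"),
}

#: Group hypothesized to carry higher heat risk, per variable (binary "yes";
#: for categorical variables the most-restrictive / private level).
CHARACTERISTIC_RISK_LEVELS = {
    **{k: "yes" for k, v in CHARACTERISTIC_KINDS.items() if v == "binary"},
    "security_level": "maximum/high",
    "percent_leave": "none",
    "operator": "private",
}


@dataclass
class FilterStage:
    name: str
    records_in: int
    records_out: int
    excluded_ids: list = field(default_factory=list)
    note: str = ""

    def __post_init__(self):
        if self.records_out != self.records_in - len(self.excluded_ids):
            raise ValueError(
                f"stage {self.name!r}: records_out != records_in - excluded"
            )


@dataclass
class FilterLog:
    """Ordered per-stage record accounting for cohort construction."""

    stages: list = field(default_factory=list)

    def add(self, name, records_in, records_out, excluded_ids=(), note=""):
        self.stages.append(
            FilterStage(name, int(records_in), int(records_out), list(excluded_ids), note)
        )

    @property
    def final_count(self) -> int:
        return self.stages[-1].records_out if self.stages else 0

    def fraction_of_initial(self) -> float:
        """final cohort size / size entering the first stage."""
        if not self.stages:
            raise ValueError("empty filter log")
        return self.final_count / self.stages[0].records_in

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "records_in": s.records_in,
                    "records_out": s.records_out,
                    "n_excluded": len(s.excluded_ids),
                    "note": s.note,
                }
                for s in self.stages
            ]
        )


def _check_unique(keys, source: str):
    dup = pd.Series(keys)
    dup = dup[dup.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate key {dup.iloc[0]!r} in {source}")


def read_facilities(
    vector_path, attributes_path, key: str = "facility_id"
) -> tuple[pd.DataFrame, FilterLog]:
    """Read facility polygons (GeoJSON) and attributes (CSV), join on ``key``.

    Vector records without matching attributes are retained with attributes
    marked missing (``attributes_missing=True``): they still count toward
    population-total reporting but are excluded from statistical analyses by
    the ``require-attributes`` cohort filter. The match rate is logged.
    """
    with open(vector_path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        props = dict(feat.get("properties") or {})
        if key not in props:
            raise ValueError(f"feature without key column {key!r} in {vector_path}")
        try:
            geom = shape(feat["geometry"])
        except Exception as e:  # pragma: no cover - malformed input
            raise ValueError(f"unreadable geometry for {props.get(key)!r}: {e}") from e
        if geom.is_empty or not geom.is_valid:
            raise ValueError(f"invalid or empty geometry for {props.get(key)!r}")
        props["geometry"] = geom
        rows.append(props)
    vec = pd.DataFrame(rows)
    if vec.empty:
        raise ValueError(f"no features in {vector_path}")
    vec[key] = vec[key].astype(str)
    _check_unique(vec[key], str(vector_path))

    attrs = pd.read_csv(attributes_path, dtype={key: str})
    if key not in attrs.columns:
        raise ValueError(f"key column {key!r} missing from {attributes_path}")
    _check_unique(attrs[key], str(attributes_path))

    merged = vec.merge(attrs, on=key, how="left", suffixes=("", "_attr"), indicator=True)
    merged["attributes_missing"] = merged.pop("_merge") == "left_only"
    merged = merged.set_index(key, drop=False)

    n = len(merged)
    n_matched = int((~merged["attributes_missing"]).sum())
    log = FilterLog()
    log.add(
        "attribute_join",
        n,
        n,
        note=f"matched {n_matched}/{n} ({100.0 * n_matched / n:.1f}%)",
    )
    return merged, log


_KNOWN_FILTERS = ("exclude-states", "require-complete-demographics", "require-attributes")


def apply_cohort_filters(
    records: pd.DataFrame, filters, log: FilterLog | None = None
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply an ordered list of cohort filters, logging per-stage counts.

    Each filter is a name or ``(name, params)`` pair:

    - ``exclude-states`` (params: ``states``, default ``("AK", "HI")``)
    - ``require-attributes`` — drop records with no matched attribute row
    - ``require-complete-demographics`` — drop records missing any of the
      eight race/ethnicity counts
    """
    if log is None:
        log = FilterLog()
    df = records
    for spec in filters:
        name, params = (spec, {}) if isinstance(spec, str) else (spec[0], dict(spec[1]))
        if name not in _KNOWN_FILTERS:
            raise ValueError(f"unknown cohort filter: {name!r}")
        n_in = len(df)
        if name == "exclude-states":
            states = set(params.get("states", ("AK", "HI")))
            keep = ~df["state"].isin(states)
        elif name == "require-attributes":
            keep = ~df["attributes_missing"].astype(bool)
        else:  # require-complete-demographics
            cols = [c for c in CENSUS_CATEGORIES if c in df.columns]
            if len(cols) < len(CENSUS_CATEGORIES):
                missing = set(CENSUS_CATEGORIES) - set(cols)
                raise ValueError(f"demographic columns missing from table: {missing}")
            keep = df[list(CENSUS_CATEGORIES)].notna().all(axis=1)
        excluded = df.index[~keep].tolist()
        df = df[keep]
        log.add(name, n_in, len(df), excluded)
    return df, log


def recode_demographics(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse the eight census categories to four analysis groups.

    Returns a frame indexed like ``records`` with columns ``white_nh``,
    ``black_nh``, ``hispanic``, ``nonwhite_nh`` (sum of the six non-white,
    non-Hispanic categories), ``total`` (sum of all eight) and ``complete``
    (all eight source counts present). Counts of incomplete rows are NaN.
    """
    demog = records[list(CENSUS_CATEGORIES)].astype(float)
    if (demog < 0).any().any():
        col = (demog < 0).any()
        raise ValueError(f"negative demographic count in column {col.idxmax()!r}")
    complete = demog.notna().all(axis=1)
    out = pd.DataFrame(index=records.index)
    out["white_nh"] = demog["white_nh"]
    out["black_nh"] = demog["black_nh"]
    out["hispanic"] = demog["hispanic"]
    out["nonwhite_nh"] = demog[list(NONWHITE_NH_COMPONENTS)].sum(axis=1, min_count=6)
    out["total"] = demog.sum(axis=1, min_count=8)
    out["complete"] = complete
    out.loc[~complete, ["white_nh", "black_nh", "hispanic", "nonwhite_nh", "total"]] = np.nan
    return out
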