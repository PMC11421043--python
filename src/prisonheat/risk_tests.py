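"""Exposure comparisons across facility-level risk characteristics.

Implements the test-selection scheme used for facility heat-exposure
comparisons:

- binary characteristic: unpaired two-sample comparison of mean exposure.
  The Wilcoxon rank-sum (Mann–Whitney U) test replaces the t-test when the
  data look nonparametric AND at least one group has fewer than ``small_n``
  facilities; otherwise Welch's unequal-variance t-test (pooled-variance t
  available behind a flag).
- multi-level characteristic: one-way ANOVA, switching to Welch's ANOVA when
  a variance-homogeneity screen rejects; a significant omnibus is followed by
  pairwise post-hoc tests (Tukey HSD after ANOVA, Games–Howell after Welch).

"Nonparametric" is operationalized as a per-group Shapiro–Wilk screen and
"depending on the variable's distribution" as a Brown–Forsythe (median-
centered Levene) screen; both screen decisions are recorded in every result.
No correction is applied across the battery of 17 variables; a Benjamini–
Hochberg adjusted column is additionally emitted, labelled as an extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .facilities import CHARACTERISTIC_KINDS, CHARACTERISTIC_RISK_LEVELS

__all__ = [
    "TestPolicy",
    "TestSelection",
    "ComparisonResult",
    "select_test",
    "compare_binary",
    "compare_multigroup",
    "run_battery",
    "battery_frame",
]


@dataclass
class TestPolicy:
    """Knobs of the test-selection scheme."""

    alpha: float = 0.05
    small_n: int = 30  # nonparametric switch needs min group n below this
    normality_alpha: float = 0.05
    variance_test_alpha: float = 0.05
    pooled_t: bool = False  # classic pooled-variance t instead of Welch

    def __post_init__(self):
        for name in ("alpha", "normality_alpha", "variance_test_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class TestSelection:
    test: str  # "t" | "wilcoxon" | "anova" | "welch_anova"
    screens: dict = field(default_factory=dict)


@dataclass
class ComparisonResult:
    variable: str
    group_labels: list
    ns: list
    means: list
    sds: list
    medians: list
    difference: float  # binary case: risk group mean − counterpart mean (°F)
    test_used: str
    statistic: float
    p_value: float
    significant: bool
    screens: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    note: str = ""


def _normal_screen(values: np.ndarray, alpha: float) -> bool:
    """True if the sample passes the Shapiro–Wilk normality screen.

    Samples too small or degenerate to test (n < 3, constant) fail the screen.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 or np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(values)
    return bool(p >= alpha)


def select_test(groups, policy: TestPolicy = TestPolicy()) -> TestSelection:
    """Choose the comparison test for a list of per-group exposure arrays."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    ns = [g.size for g in groups]
    if len(groups) == 2:
        normal = [_normal_screen(g, policy.normality_alpha) for g in groups]
        nonparam = not all(normal)
        small = min(ns) < policy.small_n
        test = "wilcoxon" if (nonparam and small) else "t"
        return TestSelection(
            test=test,
            screens={
                "normality": normal,
                "normality_alpha": policy.normality_alpha,
                "min_n": min(ns),
                "small_n_threshold": policy.small_n,
            },
        )
    if all(np.ptp(g) == 0 for g in groups):
        # Levene is undefined on all-constant data; equal variances trivially hold
        homogeneous, p_lev = True, 1.0
    else:
        _, p_lev = stats.levene(*groups, center="median")
        homogeneous = p_lev >= policy.variance_test_alpha
    return TestSelection(
        test="anova" if homogeneous else "welch_anova",
        screens={
            "levene_p": float(p_lev),
            "variance_test_alpha": policy.variance_test_alpha,
        },
    )


def _describe(groups):
    means = [float(np.mean(g)) for g in groups]
    sds = [float(np.std(g, ddof=1)) for g in groups]
    medians = [float(np.median(g)) for g in groups]
    return means, sds, medians


def compare_binary(
    variable: str,
    groups: dict,
    policy: TestPolicy = TestPolicy(),
    force_test: str | None = None,
) -> ComparisonResult:
    """Two-group comparison; the first key of ``groups`` is the group with the
    hypothesized higher heat risk, so ``difference`` = first − second mean.

    ``force_test`` ("t" or "wilcoxon") bypasses the selection scheme, e.g. to
    report a rank test regardless of what the normality screen concludes.
    """
    labels = list(groups)
    if len(labels) != 2:
        raise ValueError("compare_binary needs exactly two groups")
    vals = [np.asarray(groups[k], dtype=float) for k in labels]
    if force_test is not None:
        if force_test not in ("t", "wilcoxon"):
            raise ValueError(f"unknown forced test: {force_test!r}")
        sel = TestSelection(test=force_test, screens={"forced": True})
    else:
        sel = select_test(vals, policy)
    means, sds, medians = _describe(vals)
    if sel.test == "t":
        res = stats.ttest_ind(vals[0], vals[1], equal_var=policy.pooled_t)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided", method="auto")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        variable=variable,
        group_labels=labels,
        ns=[v.size for v in vals],
        means=means,
        sds=sds,
        medians=medians,
        difference=means[0] - means[1],
        test_used=sel.test,
        statistic=stat,
        p_value=p,
        significant=bool(p < policy.alpha),
        screens=sel.screens,
    )


def compare_multigroup(
    variable: str,
    groups: dict,
    policy: TestPolicy = TestPolicy(),
) -> ComparisonResult:
    """Omnibus comparison of ≥3 groups with assumption-matched post-hoc tests.

    Tukey HSD follows a significant one-way ANOVA; Games–Howell follows a
    significant Welch ANOVA. Post-hoc p-values are the methods' own adjusted
    values.
    """
    labels = list(groups)
    if len(labels) < 3:
        raise ValueError("compare_multigroup needs at least three groups")
    vals = [np.asarray(groups[k], dtype=float) for k in labels]
    sel = select_test(vals, policy)
    means, sds, medians = _describe(vals)

    long = pd.DataFrame(
        {
            "exposure": np.concatenate(vals),
            "grp": np.repeat(labels, [v.size for v in vals]),
        }
    )
    if sel.test == "anova":
        res = stats.f_oneway(*vals)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        aov = pg.welch_anova(data=long, dv="exposure", between="grp")
        stat, p = float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])

    posthoc = None
    if p < policy.alpha:
        if sel.test == "anova":
            ph = pg.pairwise_tukey(data=long, dv="exposure", between="grp")
            pcol = "p_tukey"
        else:
            ph = pg.pairwise_gameshowell(data=long, dv="exposure", between="grp")
            pcol = "pval"
        posthoc = pd.DataFrame(
            {
                "group_a": ph["A"],
                "group_b": ph["B"],
                "diff": ph["diff"],
                "p_adj": ph[pcol],
                "significant": ph[pcol] < policy.alpha,
            }
        )
    return ComparisonResult(
        variable=variable,
        group_labels=labels,
        ns=[v.size for v in vals],
        means=means,
        sds=sds,
        medians=medians,
        difference=float("nan"),
        test_used=sel.test,
        statistic=stat,
        p_value=p,
        significant=bool(p < policy.alpha),
        screens=sel.screens,
        posthoc=posthoc,
    )


def _untestable(variable, labels, ns, note) -> ComparisonResult:
    return ComparisonResult(
        variable=variable,
        group_labels=list(labels),
        ns=list(ns),
        means=[],
        sds=[],
        medians=[],
        difference=float("nan"),
        test_used="untestable",
        statistic=float("nan"),
        p_value=float("nan"),
        significant=False,
        note=note,
    )


def run_battery(
    data: pd.DataFrame,
    exposure_col: str = "p90_tmax",
    variables=None,
    policy: TestPolicy = TestPolicy(),
) -> list[ComparisonResult]:
    """One comparison per characteristic over a cohort table.

    ``data`` holds one row per facility with the exposure column and the
    characteristic columns. Missing attribute values are excluded pairwise
    per variable. Variables whose groups are too small or too few are flagged
    ``untestable`` and the battery continues. No multiple-testing correction
    is applied across variables (see ``battery_frame`` for the labelled
    Benjamini–Hochberg extension column).
    """
    if variables is None:
        variables = [v for v in CHARACTERISTIC_KINDS if v in data.columns]
    results = []
    for var in variables:
        if var not in data.columns:
            results.append(_untestable(var, [], [], "column absent"))
            continue
        sub = data[[exposure_col, var]].dropna()
        levels = CHARACTERISTIC_KINDS.get(var)
        if levels == "binary":
            order = ["yes", "no"]
        elif levels is not None:
            order = list(levels)
        else:
            order = sorted(sub[var].unique())
        # hypothesized-risk group first so binary differences read risk − other
        risk = CHARACTERISTIC_RISK_LEVELS.get(var)
        if risk in order:
            order = [risk] + [l for l in order if l != risk]
        present = [l for l in order if (sub[var] == l).any()]
        groups = {l: sub.loc[sub[var] == l, exposure_col].to_numpy() for l in present}
        ns = [len(g) for g in groups.values()]
        if len(groups) < 2 or any(n < 2 for n in ns):
            results.append(_untestable(var, groups, ns, "group too small or absent"))
            continue
        if len(groups) == 2:
            results.append(compare_binary(var, groups, policy))
        else:
            results.append(compare_multigroup(var, groups, policy))
    return results


def battery_frame(results, bh_extension: bool = True) -> pd.DataFrame:
    """Tabular battery summary; optionally adds a Benjamini–Hochberg adjusted
    p-value column (an extension beyond the per-variable α = 0.05 scheme,
    clearly labelled)."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "groups": "|".join(map(str, r.group_labels)),
                "ns": "|".join(map(str, r.ns)),
                "means_f": "|".join(f"{m:.3f}" for m in r.means),
                "difference_f": r.difference,
                "test": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "screens": str(r.screens),
                "note": r.note,
            }
        )
    df = pd.DataFrame(rows).set_index("variable")
    if bh_extension:
        testable = df["p_value"].dropna()
        if len(testable):
            from statsmodels.stats.multitest import multipletests

            _, p_adj, _, _ = multipletests(testable.values, method="fdr_bh")
            df["p_bh_extension"] = pd.Series(p_adj, index=testable.index)
    return df
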