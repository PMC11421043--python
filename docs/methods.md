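# Methods

## Problem and scope

`prisonheat` quantifies summer heat exposure at carceral facilities from a
gridded daily temperature product, and relates that exposure to who is
incarcerated (demographics) and to facility-level conditions hypothesized to
modify heat risk (court-order flags, labor assignments, security regime,
operator). The package covers the full chain: reading CF-style daily
tmax/tmin grids, restricting to the 1 June – 31 August summer window,
area-weighted zonal extraction over facility polygons, four heat metrics,
cohort filtering and demographic recoding, population-weighted exposure and
extreme-set contrasts, and a test-selection battery across 17 facility
characteristics. A synthetic generator emulates all three input kinds so
every stage is testable against known ground truth.

## Calendar

The target data product uses a 365-day ("no-leap") calendar: every year has
365 days and 31 December is dropped in leap years. Dates are therefore
carried as explicit `(year, month, day)` integer triples rather than epoch
offsets, and the summer window always contains exactly 92 days. Climate files
are NetCDF (classic format, written through xarray's scipy backend) with
integer `year`/`month`/`day` coordinates along `time`, which keeps reads
independent of any calendar-aware datetime library.

## Zonal extraction

Grid cells are boxes centered on their coordinates with half-cell edges (CF
convention). The default polygon→cell rule weights each cell by
area(polygon ∩ cell) / total intersection area; a polygon that intersects no
cell interior (a sliver, or a degenerate rectangle) falls back to the single
cell containing its centroid, and the mode used is recorded. Area weighting
is the default because facility polygons are near the 1-km cell scale, making
the choice material; centroid mode is available in the pipeline config.
Masked (NaN) cells are renormalized out day by day; a facility-day with no
valid cell is an error rather than a silent gap. The daily mean is
`(tmax + tmin) / 2`, the standard derivation when only daily extremes exist.

## The four heat metrics

For a facility's summer daily series in °F, with analysis years 2020–2023 and
baseline years 1990–2019 by default:

1. **Days above 85 °F** — days per summer with daily mean strictly greater
   than 85 °F, averaged over the analysis years. 85 °F is a common upper
   limit in carceral thermoregulation policies. The "at least one such day in
   any analysis year" flag is also exposed for cohort exceedance shares.
2. **p90 of daily tmax** — the 90th percentile of daily maximum temperature
   within each summer, averaged across analysis years.
3. **Anomaly** — analysis-period average p90 minus the 30-year baseline
   average p90 at the same location; a facility-local warming signal.
4. **Risk days** — total analysis-period days whose daily mean strictly
   exceeds the facility's baseline mean summer temperature by more than
   10 °F. Epidemiological work on prison mortality associates each such day
   with a 5.2% increase in total mortality; that constant travels with the
   output as metadata and is never computed here.

Numerical conventions, pinned because cross-implementation agreement requires
them: percentiles use linear interpolation between order statistics (sorted
rank position `1 + 0.9·(n−1)`); per-summer percentiles are averaged across
years rather than pooled (a pooled mode exists behind a config flag and is
labelled in provenance); both threshold metrics use strict `>` so boundary
days do not count; standard deviations use the n−1 denominator. The risk-day
baseline uses the daily mean over 1990–2019; a tmax-based variant is a config
option since the underlying definition does not pin the variable.

## Cohort construction

Facility polygons (GeoJSON) and the attribute table (CSV) join exactly on a
shared key; probabilistic record linkage between boundary and census sources
is out of scope and must be resolved upstream. Unmatched polygons are kept —
they still receive metrics and count toward population totals — but are
flagged and removed from statistical analyses by the `require-attributes`
filter. The standard filter chain mirrors cohort construction in facility
heat studies: drop Alaska/Hawaii, drop unmatched records, drop records with
incomplete race/ethnicity data. Every stage logs in/out counts and excluded
ids, and the log reconciles exactly to the final cohort size.

The eight census race/ethnicity categories are recoded to four analysis
groups: white non-Hispanic and Hispanic pass through, and the six remaining
categories (including "additional categories") sum to a non-white,
non-Hispanic group; Black non-Hispanic is additionally reported on its own.
A facility missing any source category is flagged incomplete and its recoded
counts are unusable. Facilities with attributes but zero total population are
retained for metrics and naturally drop out of population-weighted exposure
(zero weight).

## Equity measures

Population-weighted exposure per group g is
`T_g = Σ_i T_i·p_{i,g} / Σ_i p_{i,g}` over facilities with complete data.
Extreme-set contrasts rank facilities by exposure and compare the pooled
demographic composition of the top-k and bottom-k sets (k = 10, or the
decile k = floor(N/10)); pooled composition (aggregate counts) is the default
with a per-facility-mean mode available, because the aggregation underlying
published composition contrasts is not uniquely determined. Ranking sorts
once, ascending by (exposure, facility id): the id tie-break makes output a
pure function of the data, and taking the head and tail of a single sort
keeps the two sets disjoint even when ties span a boundary.

## Test selection for facility characteristics

Binary characteristics compare mean exposure between holders and non-holders:
Welch's unequal-variance t-test by default (a pooled-variance flag exists),
replaced by the Wilcoxon rank-sum test exactly when the data look
nonparametric **and** some group has fewer than 30 facilities. Multi-level
characteristics use one-way ANOVA, switching to Welch's ANOVA when variance
homogeneity is rejected; significant omnibus results are followed by
assumption-matched post-hoc tests (Tukey HSD after ANOVA, Games–Howell after
Welch). Because "nonparametric" and "depending on the variable's
distribution" are not self-defining, they are operationalized as explicit
screens — per-group Shapiro–Wilk at α = 0.05 (groups with n < 3 or constant
values fail it) and Brown–Forsythe (median-centered Levene) at α = 0.05 — and
every result records the screen outcomes. These are explicit substitutes, not
reconstructions of any particular prior analysis. α = 0.05 throughout. No
correction is applied across the 17-variable battery; a Benjamini–Hochberg
column is additionally emitted, labelled as an extension. Small-sample
Wilcoxon p-values are exact (verified against exhaustive rank-assignment
enumeration up to n = 5 per group).

The measured type-I error of the full selection-then-test procedure under
null simulations is reported by `experiments.null_battery_type1` rather than
assumed, since the data-driven switch makes the nominal level approximate.

## Synthetic generator

Per cell-day, in °F:

```
daily_mean = base(cell) + seasonal(day) + trend·(year − y0) + heatwave + noise
tmax, tmin = daily_mean ± diurnal_range/2
```

- `base` — climatological summer-mean field; the `two_zone_base` helper
  builds a cool west half and hot east half (defaults 80/86 °F) so exposure
  associations can be planted.
- `seasonal` — a half-sine over the 92-day summer window, zero outside it.
  The shape is documented in the config sidecar; any smooth per-year-identical
  shape cancels in the anomaly and integrates out of expectations.
- `trend` — uniform warming, default 0.05 °F/yr (a contemporary-warming
  order of magnitude).
- `heatwave` — additive rectangular events `(year, start, length, amplitude)`
  constrained to the summer window.
- `noise` — i.i.d. Gaussian per cell-day, default SD 1.5 °F.

Working internally in °F keeps ground-truth arithmetic exact; the °C→°F
conversion belongs to the I/O layer and is tested separately with fixed
analytic values. Facilities are axis-aligned rectangles (0.4–1.6 cells on a
side) so the area-weight oracle is computable by hand. Demographic counts are
multinomial draws from per-region mixes shaped like US prison demographics,
with the hot region carrying a larger Hispanic share; characteristic
prevalences default to realistic rarities (court-order flags ~3–6%,
agricultural labor 15%, private operator 15%). A `missingness_rate` blanks
all eight race/ethnicity counts for a random subset, and an
`ExposureAssociation` rule places facilities holding a chosen characteristic
level in the hot half with configurable probability.

Closed-form recovery targets (`expected_metrics`): the expected anomaly is
exactly `trend × (mean(analysis years) − mean(baseline years))` — 17·trend
for 2020–2023 vs 1990–2019 — for any noise level, because per-year noise
distributions are identical and cancel. Expected exceedance counts use the
Gaussian day-wise probability Φ((μ_d − threshold)/σ) (exact for days-above;
for risk days the baseline mean is treated as known, an O(σ/√(92·30))
approximation). The expected p90 is the p90 of the noise-free daily means —
exact at σ = 0 and first-order otherwise; recovery tests therefore lean on
the anomaly and the count metrics, whose expectations are exact.

What the generator does *not* emulate: real spatial autocorrelation of
weather (noise is independent across cells and days), humidity, topography,
urban heat islands, indoor temperatures or cooling infrastructure, and
population dynamics. Passing recovery tests therefore demonstrates that the
estimators are unbiased and correctly wired under the stated model, not that
any particular real-world cohort would show the same effect sizes.

## Validation problem sizes

The validation suite sizes its simulations to exercise the statistics while
staying desk-scale: anomaly recovery uses a 12×12 grid, 120 one-cell
facilities and 34 years at daily resolution (trends 0.02/0.05/0.1 °F/yr,
recovery required within 3 standard errors of 17·trend); planted-gap power
uses 2 °F gaps with within-region exposure SD 2 °F at n = 100 per group over
200 replicates (≥95% recovery required); the null battery runs 1,000
replicate cohorts of 200 facilities (17,000 tests; observed significance
share required inside [0.03, 0.07] at nominal α = 0.05, the slack allowing
for the discrete small-sample tests the selection scheme can choose).

## Degenerate inputs and tie-breaks

- `tmax < tmin` anywhere is a validation error naming the first offending
  time/cell index; a missing units attribute is an error, never a guess.
- A facility polygon entirely outside the grid extent is an error; slivers
  fall back to centroid sampling.
- Single-facility states report SD as missing (sample SD undefined at n = 1).
- Groups with n < 2 make a characteristic untestable; the battery flags it
  and continues.
- Exposure ties in extreme-set ranking break by ascending facility id.

## Known limitations

- The attribute join is exact-key only; no fuzzy matching.
- No raster reprojection: climate grid and facility polygons must share a
  CRS.
- Zero-population facilities contribute to metrics but not to any
  population-weighted quantity.
- The mortality interpretation of risk days is imported from prior
  literature as metadata; no health outcome is modelled.
- Percentile and baseline conventions are pinned choices among defensible
  alternatives; the pipeline records them in provenance so variant runs are
  distinguishable.
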