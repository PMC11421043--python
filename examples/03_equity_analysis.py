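"""Population-weighted exposure and hot/cool-set demographic contrasts.

Builds a 200-facility cohort whose hot half carries a 10-percentage-point
higher Hispanic share, then recovers that enrichment from the exposure
ranking alone.
"""

import numpy as np
import pandas as pd

from prisonheat.equity import compare_extremes, weighted_exposure_table

rng = np.random.default_rng(7)
n = 200
exposure = pd.Series(
    np.concatenate([rng.normal(96, 1.5, n // 2), rng.normal(86, 1.5, n // 2)]),
    index=[f"F{i:03d}" for i in range(n)],
)

rows = []
for i, fid in enumerate(exposure.index):
    hisp_share = 0.33 if i < n // 2 else 0.23  # planted hot-set enrichment
    total = 1000
    h = rng.binomial(total, hisp_share)
    w = rng.binomial(total - h, 0.45)
    nw = total - h - w
    rows.append(
        {"facility_id": fid, "white_nh": float(w), "black_nh": nw / 2.0,
         "hispanic": float(h), "nonwhite_nh": float(nw), "total": float(total),
         "complete": True}
    )
profiles = pd.DataFrame(rows).set_index("facility_id")

table = weighted_exposure_table(
    exposure, profiles[["white_nh", "black_nh", "hispanic", "nonwhite_nh"]]
)
print("population-weighted exposure (degF) per group:")
print(table.round(2).to_string())

comp = compare_extremes(exposure, profiles, decile=True)
print(f"\ntop/bottom decile size: k = {comp.k}")
print("hot - cool composition differences (percentage points):")
print(comp.differences_pp.round(1).to_string())
# The Hispanic difference recovers the planted ~10 pp gap; the weighted
# exposure for the Hispanic group sits above the other groups because its
# population concentrates in the hot half.
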