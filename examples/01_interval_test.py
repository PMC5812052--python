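"""Find the time intervals on which two groups' abundances differ.

Simulates one differentially abundant microbial feature observed in two
cohorts (15 subjects each, days 0..20), fits a negative-binomial smoothing
spline per group, and permutation-tests the area ratio on every unit
interval.  The feature is built to differ on days [1,5], [8,13] and [15,20]
and to coincide on [5,8] and [13,15] — the printed table should flag
(approximately) the former and clear the latter.
"""

import numpy as np

from longinterval import (
    SimulationConfig, TestConfig, build_time_grid, make_dataset,
    run_feature_test,
)

config = SimulationConfig(marginal="poisson", n_da_features=1,
                          n_null_features=0, rng_seed=42)
dataset = make_dataset(config)
series = dataset.feature_series("da_0001")
grid = build_time_grid(dataset.meta)

result = run_feature_test(series, grid,
                          TestConfig(n_permutations=200, rng_seed=42))

print(f"feature {result.feature_id}: groups {result.group_levels}, "
      f"{len(result.intervals)} unit intervals tested "
      f"on overlap {grid.overlap_range}")
print(f"{'interval':>12} {'AR':>7} {'p':>7} {'p.adj':>7}  verdict")
for r in result.intervals:
    verdict = f"{r.dominant_group} more abundant" if r.significant else "-"
    print(f"[{r.start:4.0f},{r.end:3.0f}] {r.ar:7.3f} {r.pvalue:7.3f} "
          f"{r.adjusted_pvalue:7.3f}  {verdict}")
print("\nmerged significant spans (start, end, dominant group):")
for span in result.merged:
    print(" ", span)
print("\nAR > 0 means group A's fitted curve encloses more area on the "
      "interval; significance is BH-adjusted across this feature's intervals.")
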