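"""Compare the three between-sample normalization methods on a toy table.

Sample s2 is sample s1 sequenced at double depth, and s3 has one feature
genuinely 8-fold up.  CSS and median-of-ratios factors absorb the depth
difference directly; TMM reports the residual compositional scaling after
library size, so the doubled replicate gets a factor of ~1.
"""

import numpy as np

from longinterval import CountTable, normalize

counts = np.array([
    [10.0, 20.0, 10.0],
    [40.0, 80.0, 40.0],
    [5.0, 10.0, 40.0],     # 8-fold up in s3
    [100.0, 200.0, 100.0],
    [25.0, 50.0, 25.0],
])
table = CountTable(counts, [f"otu{i}" for i in range(1, 6)],
                   ["s1", "s2", "s3"])

for method in ("css", "median_ratio", "tmm"):
    normalized, factors = normalize(table, method)
    vals = ", ".join(f"{s}={factors.factors[s]:.3f}"
                     for s in table.sample_ids)
    print(f"{method:>13}: {vals}")
print("\nCounts are divided by the factor, so a factor of 2 halves a "
      "double-depth sample; after normalization the replicate columns of a "
      "feature agree up to the genuine biological difference in s3.")
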