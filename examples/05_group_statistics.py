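"""Rank-based group comparison of skewed morphometry measurements.

Draws radii for the four lineage stages at the study's group sizes with a
shift in the corpus-luteum group and runs the Kruskal-Wallis omnibus test
with Dunn's post-hoc comparisons.
"""

import numpy as np

from mito3d.stats import (
    GroupedMeasurements,
    dunns_test,
    kruskal_wallis,
    summarize_mean_sem,
)

rng = np.random.default_rng(21)
data = GroupedMeasurements(
    [
        ("PF", rng.lognormal(np.log(100), 0.15, 39)),
        ("MF", rng.lognormal(np.log(100), 0.15, 22)),
        ("CH", rng.lognormal(np.log(100), 0.15, 21)),
        ("CL", rng.lognormal(np.log(125), 0.15, 24)),
    ],
    name="mean_radius_nm",
    units="nm",
)

h, df, p = kruskal_wallis(data)
print(f"Kruskal-Wallis (tie-corrected): H = {h:.3f}, df = {df}, p = {p:.4g}")

table = dunns_test(data, alpha=0.05, adjustment="bonferroni")
for pair in table.pairs:
    mark = "*" if pair.significant else ""
    print(f"  {pair.group_i} vs {pair.group_j}: z = {pair.z:+.2f}, "
          f"adjusted p = {pair.p_adjusted:.4g} {mark}")

print("\nmean +/- SEM per stage:")
for s in summarize_mean_sem(data):
    print(f"  {s['group']}: n = {s['n']}, {s['mean']:.1f} +/- {s['sem']:.1f} nm")
print()
print("Only pairs involving the shifted CL group should reach significance;")
print("the lognormal skew is why the rank-based path is the default.")
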