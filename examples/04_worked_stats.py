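"""Worked-example statistics for a small two-assay validation study.

Inputs are summary numbers of the kind such a study reports: assay
agreement r = 0.90 at baseline and r = 0.48 for change (n = 20), a
change-baseline correlation of -0.64 versus -0.06, a mean change of
-0.19 kb (SD 0.168), and duplicate measurements for reliability.
"""

import numpy as np

from telosim import (
    compare_correlations,
    icc_oneway,
    one_sample_t,
    pearson_p,
)

# Is agreement for change significantly worse than at baseline?
cmp = compare_correlations(0.90, 20, 0.48, 20)
print(f"0.90 vs 0.48 (n=20 each): z = {cmp.z_statistic:.2f}, p = {cmp.p_two_sided:.4f}")

cmp2 = compare_correlations(-0.64, 20, -0.06, 20)
print(f"-0.64 vs -0.06 (n=20 each): z = {cmp2.z_statistic:.2f}, p = {cmp2.p_two_sided:.3f}")

# Is r = 0.48 itself significant at n = 20?
print(f"r = 0.48, n = 20: p = {pearson_p(0.48, 20).p_two_sided:.3f}")

# Significance of the mean change (series with mean -0.19 kb, SD 0.168)
rng = np.random.default_rng(0)
z = rng.normal(size=20)
z = (z - z.mean()) / z.std(ddof=1)
t, p = one_sample_t(-0.19 + 0.16826 * z)
print(f"mean change -0.19 kb over 6.6 y: t = {t:.2f}, p = {p:.2g}")

# Reliability of duplicate measurements (subject SD 1, replicate SD 0.28)
table = rng.normal(0, 1, size=(40, 1)) + rng.normal(0, 0.28, size=(40, 2))
print(f"duplicate ICC(1,1): {icc_oneway(table).icc:.2f}")

print()
print("The z = 2.77 comparison shows change-score agreement is significantly")
print("below baseline agreement; the shortening of 29 bp/year is highly")
print("significant even at n = 20 when measured without proxy noise.")
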