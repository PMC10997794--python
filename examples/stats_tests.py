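"""The statistical toolbox on small worked examples.

Exact two-tailed Mann-Whitney U, Fisher's exact test, OLS slope with an
F-test, fold change of medians, and a Western-blot densitometry ratio.
"""

import numpy as np

import dsbquant as dq

# exact Mann-Whitney (combined n <= 12, no ties -> full enumeration)
res = dq.mann_whitney_u([12, 15, 18, 21], [7, 9, 10, 11])
print(f"Mann-Whitney U = {res.statistic:.0f}, two-tailed p = {res.p_value:.4f} "
      f"({res.method})")

# Fisher exact on a 2x2 classification (e.g. focus present / absent)
res = dq.fisher_exact([[9, 1], [2, 8]])
print(f"Fisher exact: odds ratio = {res.statistic:.1f}, p = {res.p_value:.4f}")

# OLS slope of focus density vs percent synapsis, F-test against slope 0
rng = np.random.default_rng(0)
x = rng.uniform(20, 95, 40)                   # percent synapsed
y = 0.004 * x + rng.normal(0.3, 0.05, 40)     # density, foci/um
res = dq.linreg_slope(x, y)
print(f"slope = {res.statistic:.5f} +/- {res.stderr:.5f} per %, "
      f"F-test p = {res.p_value:.2e}")

# fold change of medians and band densitometry
print(f"fold change of medians: {dq.fold_change_of_medians([10, 12, 14], [5, 6, 7]):.2f}")
print(f"slow/fast band ratio:   {dq.densitometry_ratio(10, 6, 2, 2):.2f}")
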