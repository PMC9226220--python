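"""The rank statistics behind the figure-level comparisons.

Small worked examples of the Mann-Whitney U test (independent samples),
the Wilcoxon signed-rank test (paired samples) and the Pearson
correlation, with exact small-sample p-values by enumeration.
"""

from ervkit import mann_whitney_u, pearson_r, wilcoxon_signed_rank

res = mann_whitney_u([1.2, 1.9], [3.1, 4.4], side="less")
print(f"Mann-Whitney: U_x={res.statistic:.0f}, one-sided p={res.p_value:.4f} "
      f"({res.method}); with n=2+2 the most extreme ordering gives p=1/6")

res = wilcoxon_signed_rank([2.1, 2.8, 3.5], [1.0, 1.1, 1.2], side="greater")
print(f"signed-rank:  W+={res.statistic:.0f}, one-sided p={res.p_value:.4f} "
      f"({res.method}); all three pairs increase, p=1/8")

res = wilcoxon_signed_rank([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
print(f"all-zero differences are reported as p={res.p_value} with "
      f"n_effective={res.n_effective}, not as an error")

r = pearson_r([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
print(f"Pearson r of (1,2,3) vs (1,3,2): {r:.2f}")
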