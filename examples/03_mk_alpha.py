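"""McDonald-Kreitman validation of positive-site calls.

Contrasts fixed differences (D) against polymorphism (P) between positive
(PBS) and non-positive sites: adaptive fixation inflates D and sweeps deplete
P, so the PBS odds ratio should exceed 1.  alpha estimates the proportion of
PBS substitutions fixed by positive selection.
"""

from bindsel import MkCounts, alpha_mk, ratio_test

# counts as produced by count_div_poly on tested sites + SNPs
counts = MkCounts(D_p=50, P_p=10, D_np=100, P_np=40)

odds, p = ratio_test(counts)
print(f"2x2 table [[D_p, P_p], [D_np, P_np]] = {counts.table()}")
print(f"odds ratio: {odds:.2f} (Fisher two-sided p = {p:.3g})")
print(f"alpha = 1 - (D_np*P_p)/(D_p*P_np) = {alpha_mk(counts):.2f}")
# alpha = 0.5 here: half of the substitutions in positive sites are inferred
# to have been fixed by positive selection rather than drift.
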