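"""Contingency statistics on responsive-unit counts, as used for group
comparisons (control vs stressed) of activated/inhibited/none tables.

Runs a Pearson chi-square (no continuity correction) on a 3×2 table of
responsive-unit counts and reports the phi effect size in both conventions:
the standard sqrt(chi2/N) and the responsive-denominator variant that
divides by the number of units outside the "none" category.
"""

from cuephys import chi_square, fisher_exact, phi_effect, t_tests

# activated / inhibited / none counts for two groups of ~115 units each
table = [[13, 5, 112], [1, 1, 112]]
res = chi_square(table)
print(f"chi2({res.df}) = {res.chi2:.2f}, p = {res.p:.3f}")
print(f"phi (responsive denominator, m={res.n_responsive}) = {phi_effect(res):.2f}")
print(f"phi (total N={res.n_total}) = {phi_effect(res, 'total_N'):.2f}")

# small-count proportions use the exact test instead
print("Fisher p for [[3, 1], [0, 4]]:", round(fisher_exact([[3, 1], [0, 4]]), 3))

# mean comparisons: pooled-variance t with Cohen's d
r = t_tests([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
print(f"t({r.df}) = {r.t:.3f}, p = {r.p:.3f}, d = {r.d:.2f}")
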