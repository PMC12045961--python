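"""Elementary cohort statistics on the published outcome row.

Uses the exposure-stratified outcome counts (189 asphyxia cases among
5989 exposed episodes vs 671 among 26253 unexposed) to compute the
unadjusted odds ratio, the chi-square p-value, Wilson intervals for the
incidences, and the number needed to treat implied by the >30%-dropout
odds ratio at the cohort baseline incidence.
"""

from ctgartifact import TwoByTwo, chi_square_2x2, odds_ratio_2x2, or_to_nnt, wilson_ci

table = TwoByTwo(a=189, b=5989 - 189, c=671, d=26253 - 671)

est = odds_ratio_2x2(table)
print(f"unadjusted OR {est.or_value:.3f} "
      f"(95% CI {est.ci_lo:.3f}-{est.ci_hi:.3f}; p = {est.p:.3f})")

stat, p = chi_square_2x2(table, yates=True)
print(f"chi-square (Yates) p = {p:.3f}")

for label, k, n in (("overall", 860, 32242), ("exposed arm", 189, 5989)):
    ci = wilson_ci(k, n)
    print(f"{label} incidence {100 * ci.point:.2f}% "
          f"(Wilson 95% CI {100 * ci.lo:.2f}-{100 * ci.hi:.2f}%)")

nnt = or_to_nnt(1.58, 860 / 32242)
print(f"NNT at OR 1.58, baseline 2.67%: {nnt} cesareans per case prevented")
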