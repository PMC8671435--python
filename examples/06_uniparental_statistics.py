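"""Uniparental summaries: maternal-ancestry bounds and a patriline test.

Inverting an exact binomial acceptance region turns an observed haplogroup
count into the range of population-level maternal-ancestry proportions
consistent with it; a Yates-corrected chi-square tests whether Y-haplogroup
origin classes differ between cemeteries.
"""

from paleostrat.uniparental import maternal_ancestry_range, yates_chi2

lo, hi = maternal_ancestry_range(n=63, k=35, level=0.95)
print(f"35 of 63 individuals carry West-Eurasian-class mtDNA haplogroups:")
print(f"  compatible maternal West-Eurasian ancestry {lo:.0f}-{hi:.0f} % "
      f"(exact central 95% binomial acceptance, 1% grid)")

stat, p = yates_chi2([[10, 3], [6, 9]])
print(f"\nY-haplogroup origin by cemetery (10/3 vs 6/9):")
print(f"  Yates X2(1, N=28) = {stat:.1f}, p = {p:.2f} -> not significant; "
      f"no patriline difference between cemeteries")
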