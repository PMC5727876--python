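"""Threshold metrics, cutoff selection and a timing odds-ratio analysis.

Works on the packaged grouped intervention counts of the pre-endoscopy
Rockall score: prints sens/spec/PPV/NPV at every cutoff, the
Youden-optimal cutoff, and then the delayed-endoscopy mortality odds
ratio among high-GBS patients with its survivor cells recovered by
exhaustive search against the published statistic.
"""

from ugib_triage import metrics_at_cutoff, odds_ratio_woolf, roc_points, youden_optimal
from ugib_triage.fixtures import load_table4, timing_table

counts = load_table4("pre_e_rs")
rows = [metrics_at_cutoff(counts, c).rounded() for c in range(0, 7)]
print("Pre-E RS vs need of intervention (cutoff, sens%, spec%, ppv%, npv%):")
for m in rows:
    print(f"  >{m.cutoff}  {m.sens:6.2f}  {m.spec:6.2f}  {m.ppv:5.1f}  {m.npv:5.1f}")
print(f"Youden-optimal cutoff: >{youden_optimal(rows)}")
print(f"ROC curve has {len(roc_points(counts).points)} vertices; "
      f"area = {roc_points(counts).trapezoidal_area():.3f}")

print()
res = odds_ratio_woolf(timing_table("gbs"))
print("30-day mortality, endoscopy >24 h vs <=24 h, among GBS>9 patients:")
print(f"  OR {res.odds_ratio:.3f} [95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}], "
      f"chi2 = {res.chi2:.3f}, p = {res.p:.2g}")
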