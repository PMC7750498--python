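"""Cohort-level analysis: median (IQR) overview and nonparametric tests.

Simulates a 10-patient cohort at the study's scales (lesions 0.6-9.9 ml,
peak SUV 11.6-59.8, glands 20.4-41.8 ml), evaluates every contouring
approach per patient, and reports the overview table plus the Friedman test
with uncorrected pairwise Dunn comparisons of contour volume against the
histology reference.
"""

from petseg import run_cohort

result = run_cohort(n_patients=10, seed=1)
print(result.overview.to_string())
print()

report = result.reports["volume_ml"]
names = result.report_approaches["volume_ml"]
print(f"volume: Friedman chi2 = {report.friedman_statistic:.2f}, "
      f"p = {report.friedman_p:.2g}; pairwise vs {names[0]}:")
for pair in report.pairwise:
    if 0 in (pair.approach_i, pair.approach_j):
        other = names[pair.approach_j] if pair.approach_i == 0 else names[pair.approach_i]
        verdict = "significant" if pair.significant else "n.s."
        print(f"  {other:<16} z = {pair.z:+.2f}  p = {pair.p:.4f}  {verdict}")

# Reading the table: volumes shrink and specificity rises from the 20% to
# the 50% threshold while sensitivity and coverage fall; the 50% contour is
# significantly smaller than the histology reference whereas the 20% contour
# and the individually scaled contour are statistically indistinguishable
# from it.
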