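"""Paired cohort comparison on a small simulated cohort.

Simulates eight subjects under the scaled study scenario, measures both
acquisitions of every lesion, and runs the paired analysis: median (IQR)
per condition, two-sided Wilcoxon signed-rank test, and Bland-Altman
agreement for the volume marker.
"""

from lesionshape import bland_altman, compare_cohort
from lesionshape.synthetic import FAST_SCENARIO, cohort_marker_table

table = cohort_marker_table(n_subjects=8, scenario=FAST_SCENARIO,
                            master_seed=3)
report = compare_cohort(table, alpha=0.05)

print(f"{'marker':<18}{'7T-like median':>15}{'clinical median':>16}"
      f"{'p':>9}  sig")
for _, row in report.table.iterrows():
    print(f"{row['marker']:<18}{row['median_highquality']:>15.3f}"
          f"{row['median_clinical']:>16.3f}{row['p_value']:>9.4f}"
          f"  {'*' if row['significant'] else ''}")

vol = table[table["marker"] == "volume_ml"]
ba = bland_altman(vol["value_highquality"].to_numpy(),
                  vol["value_clinical"].to_numpy())
print(f"\nvolume agreement: mean difference {ba.mean_diff:+.2f} mL, "
      f"limits of agreement [{ba.loa_low:+.2f}, {ba.loa_high:+.2f}] mL")
print("A positive mean difference means the 7T-like arm sees larger "
      "lesions; starred rows differ significantly across the cohort.")
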