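"""Regional gray-matter volume analysis: paired tests and percent changes.

Reproduces the published worked example — the whole-gray-matter volume means
give a 1.51% increase from baseline to month 6 — then simulates a paired
9-subject volume table with a +5% change planted in the left superior
occipital gyrus and shows that the per-region analysis localizes it.
"""

from sleepfbn import percent_change, simulate_volumes, volume_region_analysis
from sleepfbn.reference import gm_volume_summary

summary = gm_volume_summary().set_index("region")
pct = percent_change(summary.loc["TOTAL", "baseline_mean"], summary.loc["TOTAL", "m6_mean"])
print(f"published total gray-matter means: {summary.loc['TOTAL', 'baseline_mean']:,.2f} "
      f"-> {summary.loc['TOTAL', 'm6_mean']:,.2f} mm^3 = {pct}% increase")

table = simulate_volumes(n_subjects=9, effect={"SOG.L": 0.05}, seed=11)
region_summary, _ = volume_region_analysis(table)
cols = ["region", "n", "baseline_mean", "6M_mean", "mean_percent_change", "p_value"]
print("\nsimulated cohort with +5% planted in SOG.L:")
print(region_summary[cols].to_string(index=False))
print("\nOnly SOG.L should show a ~5% change with a small p-value; the TOTAL row")
print("moves by the planted regional volume over the whole-brain volume (~0.04%).")
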