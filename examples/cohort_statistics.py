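"""Covariate-adjusted cohort statistics on a synthetic cohort.

Draws a 111-subject cohort (31 healthy controls; 32 RRMS, 32 SPMS and 16
PPMS patients) with designed effects: an SPMS R2t* deficit in the
hippocampus and a partial correlation of 0.4 between left-hippocampus
R2t* and the SDMT processing-speed score.  Runs the group ANCOVA and the
full correlation battery (partial Pearson/Spearman + BH-FDR) and prints
the cells that carry the designed effects.
"""

from r2tstar import CohortSpec, ancova_compare, make_cohort, run_correlation_battery

cohort, truth = make_cohort(CohortSpec(seed=1))
print("cohort:", {g: int(n) for g, n in cohort.group.value_counts().items()})

merged = truth.merge(cohort, on="subject_id")
cell = merged[(merged.region_name == "hippocampus") & (merged.hemisphere == "right")]
res = ancova_compare(cell.median_r2t_star, cell.group, cell.age, cell.gender)
print(f"\nANCOVA right hippocampus R2t* (age/gender adjusted): "
      f"F = {res.f_statistic:.1f}, p = {res.p_omnibus:.2g}")
spms = res.contrasts[res.contrasts.contrast == "SPMS-HC"].iloc[0]
print(f"  SPMS-HC contrast: {spms.estimate:+.2f} s^-1 (designed -1.2), "
      f"p = {spms.p_raw:.2g}")

battery = run_correlation_battery(truth, cohort)
sdmt = battery[(battery.test_name == "SDMT_z") & (battery.region_name == "hippocampus")
               & (battery.hemisphere == "left") & (battery.measure == "R2t*")].iloc[0]
print(f"\nSDMT vs left-hippocampus R2t* (partial Pearson | age, gender, "
      f"lesion load, treatment):")
print(f"  r = {sdmt.estimate:.2f} (designed 0.4), p_FDR = {sdmt.p_fdr:.2g}, "
      f"n = {sdmt.n}")
print(f"\nbattery cells tested: {len(battery)}; "
      f"FDR-significant: {int(battery.significant.sum())}")
print("A designed coupling should surface as significant; the ~90 null")
print("cells should almost all stay non-significant under BH-FDR.")
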