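"""Run the cohort statistics battery on a synthetic two-visit cohort.

Generates controls plus mTBI patients with two visits (14 days and 6-12
months post-injury), then reproduces the analysis chain: group tests, age
correlations, age/sex-adjusted marker-symptom association, random-intercept
mixed model for the visit effect, visit-ratio coupling, and the stepwise
logistic prediction of chronic memory problems with ROC/AUC comparison.
"""

import json

import glymkit as gk
from glymkit.pipeline import run_stats_battery

cohort = gk.make_synthetic_cohort(gk.CohortGenSpec(n_control=37, n_mtbi=44, seed=0))
print(f"cohort: {len(cohort)} rows "
      f"({cohort['subject_id'].nunique()} subjects, two visits for mTBI)\n")

results = run_stats_battery(cohort, seed=0)

age = results["age_correlations"]
print("age correlations (controls):")
print(f"  WM-ePVS vs age: r = {age['wm_epvs']['control_r']:.3f} (rises with age)")
print(f"  ALPS   vs age:  r = {age['alps_index']['control_r']:.3f} (declines with age)")

sym = results["symptom_association"]
print(f"\nsymptom count vs WM-ePVS (mTBI 14Day, age/sex-adjusted): "
      f"partial r = {sym['partial_r']:.3f}, p = {sym['p']:.4g}")

ratio = results["alps_psqi_ratio"]
print(f"ALPS ratio vs PSQI ratio (6-12Mon / 14Day): r = {ratio['r']:.3f} "
      "(rising glymphatic activity tracks improving sleep)")

pred = results["prediction"]
print(f"\nchronic memory prediction: AUC basic = {pred['auc_model1']:.3f}, "
      f"with imaging markers = {pred['auc_model2']:.3f} "
      f"(bootstrap p = {pred['bootstrap_p']:.4g})")
print("model 2 selected:", pred["model2_selected"])
print("\nfull results:")
print(json.dumps(results, indent=1))
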