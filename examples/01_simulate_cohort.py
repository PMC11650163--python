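"""Simulate a study cohort and inspect its structure.

Generates the default design — 65 typically-developing (TD) training
subjects, 39 independent TD test subjects, 195 clinical subjects with
CD/ADHD/MDD/GAD diagnosis flags — each contributing one reward-condition
and one punishment-condition row over 412 brain regions.
"""
from rewarddfh import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1))

print(f"feature table: {cohort.features.shape[0]} rows "
      f"x {cohort.features.shape[1] - 2} regions")
print(cohort.features.iloc[:4, :5].to_string(index=False))
print()
print("phenotypes per group:")
print(cohort.phenotypes.groupby("group")["subject_id"].count().to_string())
print()
print("diagnosis counts (clinical subjects, comorbidity allowed):")
clin = cohort.phenotypes[cohort.phenotypes["group"] == "clinical"]
print(clin[["CD", "ADHD", "MDD", "GAD"]].sum().to_string())
print()
gains = [cohort.truth["gain"][s] for s in clin["subject_id"]]
print(f"mean reward gain in clinical sample: {sum(gains)/len(gains):.3f} "
      "(1.0 = intact reward response; smaller = more attenuated)")
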