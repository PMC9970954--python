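"""Simulate a synthetic MS cohort with a planted disability structure.

Builds a 62-subject cohort (the reference analysis size): covariates,
two MRI scans of 36 regional outcomes per subject, three clinical visits,
and raw sensor streams for six active tests, all driven by one latent
disability factor.
"""

from digibrain import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_subjects=62, seed=1))

print(f"subjects:        {len(cohort.subjects)}")
print(f"test records:    {len(cohort.records)}")
print(f"region table:    {cohort.region_table.shape[0]} subjects x "
      f"{cohort.region_table.shape[1]} columns (36 regions + total brain volume)")
print()
print(cohort.region_table[["Thalamus", "Hippocampus", "Lateral ventricles",
                           "Cerebral white matter"]].describe().round(1))
print()
s = cohort.subjects[0]
print(f"example subject: {s.subject_id}: age {s.age:.0f}, sex {s.sex}, "
      f"BMI {s.bmi:.1f}, latent disability {s.latent_disability:+.2f}")
# The latent factor shifts every loaded region: more disability means
# smaller parenchymal volumes and larger ventricles, so downstream rank
# correlations have a known ground truth.
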