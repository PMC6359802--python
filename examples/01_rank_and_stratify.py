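"""Simulate a study, rank the cohort against its reference, stratify.

Builds a 120-patient ICI-treated NSCLC cohort plus a 167-sample reference
population, expresses every gene as a 0-100 percentile rank within the
reference, and assigns each patient a proliferation stratum (tertile of
the re-ranked 10-gene signature), a PD-L1 TPS category and cold-tumor
flags.
"""

import prolifsig as ps

study = ps.simulate_study(seed=7)
reference = study.reference
ranks = reference.rank_samples(study.cohort_expression)

eligible = ps.eligible_for_survival(study.clinical)
strata = ps.assign_strata(ranks, eligible, reference)

print(strata.head(5).round(1).to_string(index=False))
print()
print("proliferation prevalence (%):")
print((100 * strata.proliferation.value_counts(normalize=True)).round(1).to_string())
print()
print("PD-L1 strongly positive: "
      f"{100 * (strata.pd_l1 == 'strong_positive').mean():.1f}%  "
      f"(cold <15 rank: {100 * strata.cold_15.mean():.1f}%)")
# Each row is one patient: the signature rank drives the proliferation
# stratum (33/66 cuts); pd_l1 follows the 1%/50% TPS cuts; cold flags
# mark low CD8-transcript ranks.
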