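"""Outcome statistics on a simulated cohort: contingency, survival, deviance.

Compares disease-control rates between proliferation strata, estimates
5-year Kaplan-Meier curves for the proliferation x PD-L1 strata, and fits
the multivariate logistic model with its sequential analysis of deviance.
"""

import pandas as pd

import prolifsig as ps

study = ps.simulate_study(seed=7)
reference = study.reference
ranks = reference.rank_samples(study.cohort_expression)
labels = ps.classify_cohort(study.clinical)
eligible = ps.eligible_for_survival(study.clinical)
strata = ps.assign_strata(ranks, eligible, reference).set_index("patient_id")

use = labels[labels.isin(["DC", "NDC"])]
dc = use == "DC"
st = strata.loc[use.index]
mod = st.proliferation == "moderately"

res = ps.dc_contingency({
    "moderately": (int(dc[mod[mod].index].sum()), int((~dc[mod[mod].index]).sum())),
    "poorly/highly": (int(dc[mod[~mod].index].sum()), int((~dc[mod[~mod].index]).sum())),
})
print(f"DC rate moderately {res.dc_rates[0]:.1%} vs extremes {res.dc_rates[1]:.1%}: "
      f"chi2={res.statistic:.2f}, p={res.p_value:.4f}")

merged = eligible.merge(strata, on="patient_id")
for name, mask in [("moderately + strong PD-L1",
                    (merged.proliferation == "moderately")
                    & (merged.pd_l1 == "strong_positive")),
                   ("poorly/highly + not strong",
                    (merged.proliferation != "moderately")
                    & (merged.pd_l1 != "strong_positive"))]:
    sub = merged[mask]
    curve = ps.km_estimate(sub.survival_months, sub.vital_status == "dead")
    print(f"median OS, {name}: {curve.median:.1f} months (n={curve.n})")

model = pd.DataFrame({
    "dc": dc.astype(int).to_numpy(),
    "proliferation": mod.to_numpy(),
    "pd_l1": st.pd_l1.isin(["weak_positive", "strong_positive"]).to_numpy(),
    "histology": eligible.set_index("patient_id").loc[use.index, "histology"].to_numpy(),
    "race": eligible.set_index("patient_id").loc[use.index, "race"].to_numpy(),
    "sex": eligible.set_index("patient_id").loc[use.index, "sex"].to_numpy(),
    "age_category": eligible.set_index("patient_id").loc[use.index, "age_category"].to_numpy(),
})
fit = ps.fit_dc_logistic(model)
print(f"\nnull deviance {fit.null_deviance:.2f} (df {fit.null_df}); "
      f"residual {fit.residual_deviance:.2f} (df {fit.residual_df})")
print(fit.deviance_table.round(4).to_string(index=False))
# The proliferation term should absorb the largest share of deviance when
# entered first; a small sequential p marks it as the most informative
# covariate for disease control.
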