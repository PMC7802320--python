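"""Survival-SVM ranking, Cox partition and G1/G2 patient stratification.

Plants one recurrence-accelerating deletion (log HR = 1.2) among 50 nulls,
ranks deletions with the linear ranking survival SVM, splits them by the
sign of the univariate Cox log hazard ratio, stratifies patients by the
carried-count rule (G1: more recurrence-associated than not) and tests the
Kaplan-Meier separation with the log-rank test.
"""

import dsvpipe as dp

cfg = dp.SimulationConfig(
    n_cancer=300, n_control=5, m_background=51,
    planted_hazard=[dp.PlantedHazard(0, 1.2)], seed=5,
)
records, cohort, truth = dp.simulate_genotypes(cfg)
carriers = dp.build_carrier_matrix(records, cohort)
patients = cohort[cohort["cohort_label"] == "cancer"]
cm = dp.CarrierMatrix(
    data=carriers.data.loc[patients["sample_id"]], metadata=carriers.metadata
)
filled = dp.simulate_survival(cm, cfg, patients)
data = dp.SurvivalData.from_cohort(cm, filled)
print(f"patients: {len(data.time)}, observed recurrences: {data.event.sum()}")

fit = dp.fit_survival_svm(data, gamma=1.0)
top = dp.rank_prognostic_dsvs(fit.coef, data.X.columns, 10)
print(f"planted DSV {truth.hazard_dsvs[0][0]} in SVM top 10: "
      f"{truth.hazard_dsvs[0][0] in top}")

partition = dp.partition_by_hazard(top, data)
print("\ntop-ranked deletions with Cox log HR and group:")
print(partition[["dsv_id", "log_hr", "p", "group"]].round(3).to_string(index=False))
# log HR > 0 marks a deletion whose carriers recur faster.

strata = dp.stratify_patients(cm, partition)
stat, p = dp.logrank_test(data, strata["group"].to_numpy())
counts = strata["group"].value_counts().to_dict()
print(f"\nG1/G2 sizes: {counts}; log-rank statistic = {stat:.2f}, p = {p:.2e}")
# A small p confirms that counting carried risk deletions separates the
# recurrence-free-survival curves of the two patient groups.
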