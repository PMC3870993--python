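"""Standard errors for the SMR and the DRS CMF, two ways.

The theoretical SEs are binomial-variance formulae with the pooled
quantities (expected events, weights, overall rate) treated as fixed; the
bootstrap resamples each centre's patients with replacement 1000 times and
takes the standard deviation of the replicate statistics. On data
generated by the same family as the analysis model, the two agree closely;
on real data the theoretical formulae tend to run slightly high.
"""

import riskstand as rs

cohort = rs.generate_cohort(rs.make_multicentre_spec(seed=11))
model = rs.fit_risk_model(
    cohort, rs.ModelSpec(factors=("severity",), continuous=("age",))
)
risks = model.predict(cohort)
scheme = rs.build_risk_categories(risks, cohort.events, K=10)
weights = rs.category_weights(scheme, risks, cohort.events)

cfg = rs.BootstrapConfig(replicates=1000, seed=11)
boot_smr = rs.bootstrap_se(cohort, model, scheme, weights, "smr", cfg)
boot_cmf = rs.bootstrap_se(cohort, model, scheme, weights, "cmf", cfg)

print(f"{'centre':<12}{'SE(SMR) theo':>13}{'boot':>7}{'SE(CMF) theo':>14}{'boot':>7}")
for cid in cohort.centre_ids():
    m = cohort.centre_mask(cid)
    t_smr = rs.se_smr_theoretical(risks[m], risks[m].sum())
    table = rs.centre_rate_table(cohort, scheme, risks, cid)
    t_cmf = rs.se_cmf_theoretical(table, weights, cohort.overall_rate)
    print(f"{cid:<12}{t_smr:>13.3f}{boot_smr[cid].se:>7.3f}"
          f"{t_cmf:>14.3f}{boot_cmf[cid].se:>7.3f}")
print("\nSE(SMR) and SE(CMF) are of very similar size: switching from the"
      " SMR to the fairer DRS CMF costs essentially no precision here.")
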