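"""Why neither classical standardisation method is enough.

Two deterministic textbook-style configurations, evaluated exactly:

1. Direct casemix standardisation when one hospital has an empty casemix
   cell: hospital 2 is 20% worse cell-for-cell, yet its raw directly
   standardised rate comes out 20% *better*, because its effective weights
   only sum to 0.75. Renormalising the weights repairs the scale (16 per
   100) but gives each hospital its own weights.
2. Indirect standardisation (SMR) when two hospitals have *identical*
   cell-specific death rates but different casemix: the hospital with more
   high-risk patients gets the lower SMR (105 vs 112), so the SMRs are not
   comparable between hospitals.
"""

import riskstand as rs

fx1 = rs.table1_fixture()
r1, ews1 = rs.direct_casemix_rate(fx1.cells["hospital_1"], fx1.standard_weights)
r2, ews2 = rs.direct_casemix_rate(fx1.cells["hospital_2"], fx1.standard_weights)
r2n, _ = rs.direct_casemix_rate(
    fx1.cells["hospital_2"], fx1.standard_weights, renormalise=True
)

print("-- direct standardisation with a missing cell --")
print(f"hospital 1 DSR: {100 * r1:.0f} per 100   (weights used sum to {ews1:.2f})")
print(f"hospital 2 DSR: {100 * r2:.0f} per 100   (weights used sum to {ews2:.2f})")
print(f"hospital 2 DSR, weights renormalised: {100 * r2n:.0f} per 100")
print("hospital 2 is 20% worse in every cell it shares, yet its raw DSR is"
      " 20% lower: the missing Children cell silently shifts its weights.\n")

fx2 = rs.table2_fixture()
for hosp in ("hospital_A", "hospital_B"):
    o = fx2.observed_per_patient(hosp)
    e = fx2.expected_per_patient(hosp)
    print(f"{hosp}: O={o:.2f}, E={e:.2f} per patient -> SMR x100 = "
          f"{100 * rs.smr(o, e):.0f}")
print("identical performance, different casemix: the 40%-high-risk hospital"
      " gets the lower SMR, purely because its weights differ.")
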