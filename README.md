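# riskstand

Direct risk standardisation (DRS) for comparing event rates between
centres — hospitals, regions, time periods — whose patients differ in
casemix.

## The problem

Crude event-rate comparisons between centres are confounded by casemix.
The two classical repairs each fail in a characteristic way:

* **Direct casemix standardisation** combines each centre's
  casemix-cell-specific event rates with one shared weight set,
  `DSR_j = Σ_c w_c p_jc`. It breaks when a centre has *empty cells*: the
  weights actually used no longer sum to 1 and the rate is silently biased
  towards whichever cells the centre happens to populate. Renormalising
  the weights per centre restores the scale but gives every centre its own
  weights — which is exactly the unfairness it was meant to fix. It also
  cannot use continuous covariates at all.
* **Indirect standardisation** computes `SMR_j = O_j / E_j`, expected
  events coming from standard casemix-specific rates (equivalently, from a
  pooled logistic regression) applied to the centre's own casemix. Because
  each centre is weighted by its *own* casemix, SMRs of centres with
  different casemix are not strictly comparable: two centres with
  identical cell-specific death rates can receive SMRs of 105 and 112.

**Direct risk standardisation** keeps the fairness of direct
standardisation while using the same model machinery as the SMR. A
logistic casemix model fitted to the *pooled* data maps every patient to a
one-dimensional predicted risk `p_i`; the risk axis is partitioned into K
categories (preferably with approximately equal observed events per
category); each centre's observed event rate `p_jk` within category k is
combined with one shared weight vector:

    DRS_j = Σ_k w_k p_jk,        CMF_j = DRS_j / r̄,

where the natural weights `w_k` are the pooled patient proportions per
category and `r̄` is the pooled event rate. The comparative mortality
figure (CMF) is the direct analogue of the SMR, is fair under casemix
differences, and handles continuous covariates for free.

## A worked example

`python examples/worked_examples.py` evaluates the two classical failure
modes exactly:

```
-- direct standardisation with a missing cell --
hospital 1 DSR: 15 per 100   (weights used sum to 1.00)
hospital 2 DSR: 12 per 100   (weights used sum to 0.75)
hospital 2 DSR, weights renormalised: 16 per 100

hospital_A: O=0.44, E=0.42 per patient -> SMR x100 = 105
hospital_B: O=0.38, E=0.34 per patient -> SMR x100 = 112
```

Hospital 2 is 20% worse than hospital 1 in every cell it shares, yet its
raw DSR is 20% *lower* because it admits no children and so uses only 75%
of the standard weights. Hospitals A and B perform identically
cell-for-cell, yet A's higher-risk casemix earns it the lower SMR.

`python examples/drs_pipeline.py` runs the full DRS pipeline on a
simulated nine-centre cohort (2000 emergency admissions per centre, ~6%
event rate, severity strata plus a continuous age covariate):

```
centre           n    O       E    SMR  DRS rate    CMF
centre_01     2000  111   116.0   0.96    0.0536   0.95
centre_02     2000  119   118.3   1.01    0.0566   1.01
centre_03     2000  107   123.0   0.87    0.0483   0.86
centre_04     2000  130   104.6   1.24    0.0707   1.26
...
```

`O` and `E` are observed and model-expected events; SMR and CMF are both
centred at 1, and agree closely when casemix differences are moderate —
but only the CMF uses the same weights for every centre. The other
examples print the theoretical-vs-bootstrap standard errors and the
stability of the centre ranking in the number of risk categories.

## Command line

```
riskstand simulate sim.yaml -o cohort.csv
riskstand standardise run.yaml -i cohort.csv -o results.csv \
    --diagnostics diag.json --bootstrap 1000 --seed 1
riskstand sensitivity run.yaml -i cohort.csv -o cmfs.csv --k-list 5,10,25
riskstand full run.yaml --simulate sim.yaml --outdir out/
```

The YAML config declares column roles, model terms, the number of risk
categories (default 10, built with approximately equal observed events)
and the weight source; flags override. Results are written as CSV with
undefined statistics as empty fields (a centre missing a
positively-weighted risk category has *no* DRS rate, and the reason is
recorded — it is never imputed).

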