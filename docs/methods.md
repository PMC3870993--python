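# Methods

This note records the statistical model the package implements, the
choices made where the method leaves room, and what the synthetic-data
experiments do and do not demonstrate.

## The estimators

All methods share one pooled risk model. Let i index patients, j centres,
`y_i ∈ {0,1}` the event indicator, `N = Σ_j n_j`, `D = Σ_i y_i`, and
`r̄ = D/N` the pooled event rate.

**Risk model.** A logistic regression of the event on the casemix
covariates, fitted by maximum likelihood to the data aggregated across all
centres, never per centre and never with a centre term. Categorical
factors enter as reference-level dummies (reference = first level in
sorted order); continuous covariates enter linearly on the logit scale;
interactions among factors can be requested term by term or all at once
(`saturated=True`). The fitted probabilities `p_i` are the patient risks.
With an intercept present the score equations force `Σ_i p_i = D`, which
is what makes the pooled SMR exactly 1 and is checked to `1e-6·D` in the
tests. A cell-rate lookup model (`CellRateModel`) represents externally
given standard rates; with pooled observed cell rates and a saturated
logistic fit the two coincide (verified to `1e-8`), which is the classical
equivalence between regression-based and cell-based indirect
standardisation.

**SMR (indirect standardisation).** `SMR_j = O_j / E_j` with
`E_j = Σ_{i∈j} p_i`. Reported on the ratio scale; ×100 is a formatting
option.

**DRS rate and CMF.** Patients are assigned to risk categories defined on
the pooled risks (below). With category weights `w_k` (Σ w_k = 1) and
centre-by-category observed rates `p_jk = d_jk / n_jk`:

    DRS_j = Σ_k w_k p_jk,    CMF_j = DRS_j / r̄.

With patient-proportion weights the pooled cohort satisfies
`DRS = r̄` and `CMF = 1` exactly (an algebraic identity, tested to 1e-9).
A centre with `n_jk = 0` for some `w_k > 0` has an *undefined* DRS: the
package reports the offending category and never renormalises weights per
centre for DRS — doing so would reintroduce exactly the per-centre-weights
unfairness that motivates the method. The supported remedy is choosing a
smaller K for all centres jointly.

**Conventional DSR.** `DSR_j = Σ_c w_c p_jc` over casemix cells with
pooled-proportion standard weights. Both the raw rate (weights as they
are, sum possibly < 1) and the per-centre renormalised rate are reported,
together with the effective weight sum `Σ_{c: n_jc>0} w_c` — the
diagnostic that exposes the missing-cell bias. When the risk model uses a
continuous covariate the cell-based DSR is meaningless and is reported as
undefined rather than silently computed from the factors alone being
treated as the whole casemix.

## Risk categories

Four construction strategies are provided (equal width, equal patients,
equal observed events, equal predicted events) and four weight sources
(equal, patient / observed-event / predicted-event proportions). The
default is K = 10 categories with approximately equal observed events and
patient-proportion weights: equal-events categories keep events, hence
patients, in every category even at the ~5% event rates typical of
admission mortality, and ~10 categories is enough for a stable centre
ranking (see the stability experiment below) while keeping per-centre
cells populated.

Patients sharing a predicted risk can never be split across a boundary,
so equal counts are a guiding principle, not a guarantee. The cut rule is
greedy over blocks of tied risks in ascending order, with target
`remaining quantity / remaining categories`, re-computed after each cut.
Two refinements matter:

* *Nearest-to-target closing*: a category closes when extending it past
  the next tied block would land further from the target than stopping
  short. A naive "close only once the target is reached" rule collapses a
  two-point risk distribution into a single category (the low-risk block
  undershoots, the high-risk block is last, no cut is ever made), which
  destroys the method precisely in the textbook two-group setting.
* *Forced closing*: once the remaining distinct risk values are only just
  enough for the remaining categories, every block closes a category, so
  the scheme realises as many of the requested categories as ties permit.

Boundaries are stored as risk values defining half-open intervals
`[b_{k-1}, b_k)`, top interval closed, boundary values belonging to the
upper category; assignment of new risks is therefore deterministic.
Requesting more categories never yields fewer (property-tested), and
category assignment is verified against a brute-force linear scan.

## Standard errors

The theoretical SEs treat every pooled quantity (E_j, w_k, r̄, the model,
the boundaries) as fixed constants and propagate only binomial outcome
variance:

    SE(SMR_j) = sqrt(Σ_{i∈j} p_i (1 − p_i)) / E_j
    SE(CMF_j) = sqrt(Σ_k w_k² p_jk (1 − p_jk) / n_jk) / r̄

Both scale exactly as `1/sqrt(m)` under m-fold replication of a centre.
These derivations are validated empirically against the bootstrap rather
than against a printed reference: the within-centre bootstrap resamples
each centre's (risk, outcome, category) rows with replacement —
B = 1000 by default — holding the pooled model, boundaries, weights and
r̄ frozen at the original fit, and takes the SD (divisor B−1) of the
replicate statistics. Freezing the pooled fit is a deliberate choice: it
measures the sampling variability of the centre's own summary given the
standard, not the variability of the standard itself. Replicates in which
a positively-weighted category empties are dropped and counted; a centre
with more than 10% failed replicates is flagged unreliable. One master
seed spawns an independent child stream per centre (keyed by centre id),
so adding a centre never perturbs the draws of the others.

On the nine-centre synthetic cohort the theoretical SEs sit within ~13%
of the B = 1000 bootstrap for every centre, and SE(SMR) and SE(CMF) are
within a few percent of each other — switching from SMR to DRS CMF costs
essentially no precision. On real data, where the casemix model is
misspecified to some degree, the theoretical formulae can be expected to
run somewhat high relative to the bootstrap.

## The synthetic generator

`SimulationSpec` describes centres by size, casemix distribution over
factor-level cells, an odds-scale performance multiplier, optional
verbatim cell-rate overrides, and cells forced empty for structural,
organisational or random reasons; cell event probabilities can be spread
continuously with Normal covariates acting linearly on the logit (centred
at their mean, so cell rates are the rates of an average patient).
Odds-scale performance keeps probabilities in (0,1) for any multiplier
and matches the logistic analysis model.

`make_multicentre_spec` is the ready-made scenario used throughout the
tests: three severity strata with event probabilities 0.02/0.06/0.15 and
mean mix 0.50/0.35/0.15 (overall rate ≈ 5.5%, the scale of short-term
mortality after emergency admission), per-centre Dirichlet casemix
(concentration 60), log-normal performance multipliers (sd 0.15 on the
log-odds), and age ~ Normal(70, 15) years with slope 0.03 per year on the
logit. Defaults of 9 centres × 2000 patients mirror a multi-centre
emergency-admissions study; the category-stability experiment uses 50
centres × 4000 patients over 20 replicates, a deliberately scaled-down
stand-in for a national hospital system where each hospital contributes
tens of thousands of admissions.

What passing these experiments shows — and what it does not. The
generator draws outcomes from the same logistic family the analysis fits,
with independent patients and no missing data. It therefore demonstrates
the *algebraic* properties of the estimators (fairness of DRS under
casemix differences, self-consistency, SE calibration under a correct
model) but says nothing about model misspecification, within-centre
correlation, coding drift between centres, or informative missingness —
all of which affect real hospital data and any standardisation method
applied to it.

## Numerical choices and degenerate inputs

* Logistic fits: Newton iterations, parameter tolerance 1e-10, max 100
  iterations; non-convergence and perfect separation raise, with the
  candidate separating factor levels named; an optional ridge penalty
  (default off) exists for deliberately degenerate synthetic inputs.
* Factor levels are exact strings after whitespace trimming; unseen
  levels at prediction raise rather than falling back to the reference.
* Undefined statistics are `None` with a recorded reason, serialised as
  empty CSV fields — never 0 and never silent NaN.
* Rates are double precision; worked-example checks are at 1e-9 after
  scaling to printed units; results CSVs round-trip floats exactly
  (`repr` format, `float_precision="round_trip"` on read).
* Rank correlations between category counts use Spearman rho with average
  ranks for ties; centres with undefined CMFs at some K are dropped from
  correlations involving that K, with a warning.
* Listwise deletion of rows with missing declared values on ingestion,
  with the dropped count kept on the cohort.

## Known limitations

* The equal-events cut rule is one reasonable realisation of a guiding
  principle; other tie-handling rules produce slightly different
  boundaries (all are deterministic and shared by every centre, which is
  what fairness requires).
* Theoretical SEs ignore the sampling variability of the pooled standard
  (model, weights, r̄); confidence intervals beyond ±1.96·SE, funnel
  plots and over-dispersion adjustments are out of scope.
* The bootstrap does not refit the risk model per replicate.
* No shrinkage/hierarchical estimation: small centres get honest but
  noisy estimates, or an explicit "undefined" when categories empty.
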