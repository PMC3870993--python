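"""DRS rate, CMF, SMR, conventional DSR, and the full pipeline."""

import numpy as np
import pandas as pd
import pytest

import riskstand as rs
from riskstand.standardisers import (
    CentreRateTable,
    category_sensitivity,
    centre_rate_table,
    cmf,
    direct_casemix_rate,
    drs_rate,
    smr,
    standardise_all,
)


class TestDrsRate:
    def test_hand_weighted_sum(self):
        table = CentreRateTable("c", n=np.array([10, 10]), d=np.array([2, 4]))
        w = rs.CategoryWeights(weights=np.array([0.5, 0.5]), source="equal")
        assert drs_rate(table, w) == pytest.approx(0.30)

    def test_single_category_collapses_to_crude_rate(self):
        table = CentreRateTable("c", n=np.array([250]), d=np.array([20]))
        w = rs.CategoryWeights(weights=np.array([1.0]), source="equal")
        assert drs_rate(table, w) == pytest.approx(20 / 250)

    def test_empty_weighted_category_is_not_computable(self):
        table = CentreRateTable("c", n=np.array([10, 0]), d=np.array([2, 0]))
        w = rs.CategoryWeights(weights=np.array([0.5, 0.5]), source="equal")
        with pytest.raises(rs.NotComputableError, match="category 2"):
            drs_rate(table, w)

    def test_zero_weight_empty_category_is_fine(self):
        table = CentreRateTable("c", n=np.array([10, 0]), d=np.array([2, 0]))
        w = rs.CategoryWeights(weights=np.array([1.0, 0.0]), source="equal")
        assert drs_rate(table, w) == pytest.approx(0.2)

    def test_pooled_drs_with_patient_weights_is_overall_rate(
        self, multicentre_pipeline
    ):
        cohort, _, risks, scheme, weights = multicentre_pipeline
        pooled = centre_rate_table(cohort, scheme, risks, None)
        assert drs_rate(pooled, weights) == pytest.approx(
            cohort.overall_rate, abs=1e-12
        )


class TestCmfSmr:
    def test_cmf_of_overall_rate_is_one(self):
        assert cmf(0.05, 0.05) == pytest.approx(1.0)

    def test_cmf_direct_division(self):
        assert cmf(0.06, 0.05) == pytest.approx(1.2)

    def test_cmf_requires_positive_overall_rate(self):
        with pytest.raises(rs.ParameterError):
            cmf(0.05, 0.0)

    def test_smr_observed_equals_expected(self):
        assert smr(42, 42.0) == pytest.approx(1.0)

    def test_smr_requires_positive_expected(self):
        with pytest.raises(rs.ParameterError):
            smr(3, 0.0)

    def test_two_cell_worked_example_printed_values(self):
        # identical cell-specific death rates, different casemix: the
        # hospital with more high-risk patients gets the *lower* SMR
        fx = rs.table2_fixture()
        a = smr(fx.observed_per_patient("hospital_A"), fx.expected_per_patient("hospital_A"))
        b = smr(fx.observed_per_patient("hospital_B"), fx.expected_per_patient("hospital_B"))
        assert round(a * 100) == 105
        assert round(b * 100) == 112
        assert a < b


class TestDirectCasemixRate:
    def test_three_cell_worked_example(self):
        fx = rs.table1_fixture()
        rate, ews = direct_casemix_rate(fx.cells["hospital_1"], fx.standard_weights)
        assert rate * 100 == pytest.approx(15.0)
        assert ews == pytest.approx(1.0)

    def test_missing_cell_biases_raw_rate_and_weight_sum(self):
        fx = rs.table1_fixture()
        rate, ews = direct_casemix_rate(fx.cells["hospital_2"], fx.standard_weights)
        assert rate * 100 == pytest.approx(12.0)
        assert ews == pytest.approx(0.75)
        # the hospital that is 20% worse cell-for-cell looks 20% better
        rate1, _ = direct_casemix_rate(fx.cells["hospital_1"], fx.standard_weights)
        assert rate == pytest.approx(0.8 * rate1)

    def test_renormalisation_partially_repairs(self):
        fx = rs.table1_fixture()
        rate, ews = direct_casemix_rate(
            fx.cells["hospital_2"], fx.standard_weights, renormalise=True
        )
        assert rate * 100 == pytest.approx(16.0)
        assert ews == pytest.approx(0.75)

    def test_complete_centre_renormalised_equals_raw(self):
        fx = rs.table1_fixture()
        raw, _ = direct_casemix_rate(fx.cells["hospital_1"], fx.standard_weights)
        renorm, _ = direct_casemix_rate(
            fx.cells["hospital_1"], fx.standard_weights, renormalise=True
        )
        assert raw == renorm

    def test_weights_must_sum_to_one(self):
        fx = rs.table1_fixture()
        with pytest.raises(rs.ValidationError, match="sum to 1"):
            direct_casemix_rate(fx.cells["hospital_1"], {("Children",): 0.5})

    def test_no_populated_cells_not_computable(self):
        with pytest.raises(rs.NotComputableError):
            direct_casemix_rate(
                [rs.CasemixCell(("Adults",), 0, 0)],
                {("Adults",): 1.0},
            )


class TestStandardiseAll:
    def test_single_centre_self_standardisation(self, two_factor_frame):
        df = two_factor_frame.copy()
        df["centre"] = "only"
        cohort = rs.cohort_from_frame(df, rs.CovariateSpec(factors=("age_band", "sex")))
        model = rs.fit_risk_model(cohort, rs.ModelSpec(factors=("age_band", "sex")))
        risks = model.predict(cohort)
        scheme = rs.build_risk_categories(risks, cohort.events, K=3)
        w = rs.category_weights(scheme, risks, cohort.events)
        (res,) = standardise_all(cohort, model, scheme, w)
        assert res.smr == pytest.approx(1.0, abs=1e-6)
        assert res.cmf == pytest.approx(1.0, abs=1e-9)
        assert res.effective_weight_sum == pytest.approx(1.0)
        assert res.dsr_raw == pytest.approx(res.dsr_renormalised)

    def test_identical_performance_different_casemix(self):
        """Two centres with identical category-specific rates but different
        casemix get identical DRS CMFs, while their SMRs against external
        standard rates differ (higher-risk mix -> lower SMR)."""
        fx = rs.table2_fixture()
        cohort = rs.generate_cohort(fx.as_simulation_spec(n_per_centre=6000, seed=3))
        # exact two-point risk distribution: saturated one-factor fit
        model = rs.fit_risk_model(
            cohort, rs.ModelSpec(factors=("risk_group",), saturated=True)
        )
        risks = model.predict(cohort)
        scheme = rs.build_risk_categories(risks, cohort.events, K=2)
        w = rs.category_weights(scheme, risks, cohort.events)
        results = {r.centre_id: r for r in standardise_all(cohort, model, scheme, w)}
        a, b = results["hospital_A"], results["hospital_B"]
        # within-category risks are constant, so DRS differences are pure
        # sampling noise in the cell rates
        assert abs(a.cmf - b.cmf) < 0.05
        std = rs.CellRateModel(factors=("risk_group",), rates=fx.standard_rates)
        smr_a = smr(a.observed, rs.expected_events(std, cohort, "hospital_A"))
        smr_b = smr(b.observed, rs.expected_events(std, cohort, "hospital_B"))
        assert smr_a < smr_b

    def test_not_computable_centre_does_not_abort_batch(self, multicentre_pipeline):
        cohort, model, risks, scheme, _ = multicentre_pipeline
        # a weight vector concentrated on a category some centre lacks
        idx = scheme.assign_indices(risks)
        counts_first = np.bincount(
            idx[cohort.centre_mask(cohort.centre_ids()[0])],
            minlength=scheme.effective_K,
        )
        bad_w = np.zeros(scheme.effective_K)
        bad_w[counts_first.argmin()] = 1.0
        # ensure at least one centre genuinely lacks that category
        df = cohort.df[~(cohort.centres == "centre_01")].copy()
        lone = cohort.df[cohort.centres == "centre_01"].head(3)
        cohort2 = rs.cohort_from_frame(pd.concat([df, lone]), cohort.spec)
        model2 = rs.fit_risk_model(
            cohort2, rs.ModelSpec(factors=("severity",), continuous=("age",))
        )
        risks2 = model2.predict(cohort2)
        scheme2 = rs.build_risk_categories(risks2, cohort2.events, K=10)
        w2 = rs.category_weights(scheme2, risks2, cohort2.events)
        results = standardise_all(cohort2, model2, scheme2, w2)
        assert len(results) == len(cohort2.centre_ids())
        tiny = [r for r in results if r.centre_id == "centre_01"][0]
        assert tiny.drs_rate is None and tiny.cmf is None
        assert "category" in tiny.notes
        others = [r for r in results if r.centre_id != "centre_01"]
        assert all(r.cmf is not None for r in others)

    def test_end_to_end_matches_independent_recomputation(self, multicentre_pipeline):
        """Scripted recomputation of every measure from raw arrays."""
        cohort, model, risks, scheme, weights = multicentre_pipeline
        results = {r.centre_id: r for r in standardise_all(cohort, model, scheme, weights)}
        idx = scheme.assign_indices(risks)
        rbar = cohort.events.mean()
        for cid in cohort.centre_ids():
            m = cohort.centres == cid
            exp = risks[m].sum()
            assert results[cid].smr == pytest.approx(cohort.events[m].sum() / exp)
            drs = 0.0
            for k in range(scheme.effective_K):
                sel = m & (idx == k)
                drs += weights.weights[k] * cohort.events[sel].mean()
            assert results[cid].drs_rate == pytest.approx(drs, abs=1e-12)
            assert results[cid].cmf == pytest.approx(drs / rbar, abs=1e-12)


class TestCategorySensitivity:
    @staticmethod
    def _cohort_and_model():
        spec = rs.make_multicentre_spec(n_centres=12, n_per_centre=1500, seed=99)
        cohort = rs.generate_cohort(spec)
        model = rs.fit_risk_model(
            cohort, rs.ModelSpec(factors=("severity",), continuous=("age",))
        )
        return cohort, model

    def test_cmfs_per_k_and_correlations_shape(self):
        cohort, model = self._cohort_and_model()
        res = category_sensitivity(cohort, model, [5, 10])
        assert res.cmfs.shape == (12, 2)
        assert res.rank_correlations.loc[5, 5] == 1.0
        assert -1.0 <= res.rank_correlations.loc[5, 10] <= 1.0

    def test_identical_cmf_vectors_across_k_correlate_perfectly(self):
        # a two-point risk distribution degenerates every K >= 2 to the same
        # two categories, so the CMF vectors are identical and rho = 1
        fx = rs.table2_fixture()
        cohort = rs.generate_cohort(fx.as_simulation_spec(n_per_centre=1200, seed=8))
        model = rs.fit_risk_model(
            cohort, rs.ModelSpec(factors=("risk_group",), saturated=True)
        )
        res = category_sensitivity(cohort, model, [2, 5, 10])
        assert np.allclose(res.cmfs[2], res.cmfs[5])
        assert res.rank_correlations.loc[2, 10] == pytest.approx(1.0)

    def test_k_below_two_rejected(self):
        cohort, model = self._cohort_and_model()
        with pytest.raises(rs.ParameterError):
            category_sensitivity(cohort, model, [1, 10])
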