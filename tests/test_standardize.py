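"""Marginal measures: averaging, weighting, closed forms, partition."""

import numpy as np
import pandas as pd
import pytest

import relstand as rs
from relstand import standardize as std
from tests.conftest import CONST_LAM0, CONST_MU, make_exponential_cohort


class TestMarginalRelativeSurvival:
    def test_single_patient_equals_conditional(self, scenario_a):
        results, _ = scenario_a
        times = np.array([1.0, 5.0])
        rec = results.model.cohort.data.iloc[[4]]
        curve = results.marginal_relative_survival(times, subset=rec, ci=None)
        np.testing.assert_allclose(
            curve.estimate,
            results.predict_relative_survival(rec, times)[0], rtol=1e-12)

    def test_marginal_is_mean_of_conditionals(self, scenario_a):
        results, _ = scenario_a
        times = np.array([0.5, 2.0, 5.0])
        curve = results.marginal_relative_survival(times, ci=None)
        cond = results.predict_relative_survival(times=times)
        np.testing.assert_allclose(curve.estimate, cond.mean(axis=0),
                                   rtol=1e-12)
        assert (curve.estimate >= cond.min(axis=0)).all()
        assert (curve.estimate <= cond.max(axis=0)).all()

    def test_unit_weights_equal_unweighted(self, scenario_a):
        results, _ = scenario_a
        times = np.array([5.0])
        n = results.model.cohort.n
        c1 = results.marginal_relative_survival(times, ci=None)
        c2 = results.marginal_relative_survival(times, ci=None,
                                                weights=np.ones(n))
        np.testing.assert_array_equal(c1.estimate, c2.estimate)

    def test_net_probability_is_one_minus_relative_survival(self, scenario_a):
        results, _ = scenario_a
        times = np.array([1.0, 5.0])
        rsurv = results.marginal_relative_survival(times, ci=None)
        netp = results.marginal_relative_survival(times, ci=None,
                                                  as_probability=True)
        np.testing.assert_allclose(netp.estimate, 1.0 - rsurv.estimate,
                                   rtol=1e-12)

    def test_empty_subset_rejected(self, scenario_a):
        results, _ = scenario_a
        with pytest.raises(ValueError, match="empty"):
            results.marginal_relative_survival(
                [5.0], subset=results.model.cohort.data.iloc[:0])

    def test_zero_weights_rejected(self, scenario_a):
        results, _ = scenario_a
        n = results.model.cohort.n
        with pytest.raises(ValueError, match="zero"):
            results.marginal_relative_survival([5.0], weights=np.zeros(n))


class TestExternalWeights:
    def test_reference_equal_to_study_reproduces_unweighted(self, scenario_a):
        results, _ = scenario_a
        data = results.model.cohort.data
        study = data["dep"].value_counts(normalize=True).to_dict()
        w = rs.external_weights(data, "dep", study)
        times = np.array([5.0])
        c_w = results.marginal_relative_survival(times, weights=w, ci=None)
        c_u = results.marginal_relative_survival(times, ci=None)
        np.testing.assert_allclose(c_w.estimate, c_u.estimate, rtol=1e-12)

    def test_weights_average_to_one_and_upweight_rare_groups(self):
        df = pd.DataFrame({"g": ["a"] * 80 + ["b"] * 20})
        w = rs.external_weights(df, "g", {"a": 0.5, "b": 0.5})
        assert np.mean(w) == pytest.approx(1.0, rel=1e-12)
        assert w[-1] > w[0]   # group b is underrepresented in the study

    def test_missing_reference_group_is_an_error(self):
        df = pd.DataFrame({"g": ["a", "b"]})
        with pytest.raises(ValueError, match="b"):
            rs.external_weights(df, "g", {"a": 1.0})


class TestAllCauseSurvival:
    def test_no_other_cause_mortality_reduces_to_relative_survival(self):
        zero = pd.DataFrame(
            [(a, y, s, 0.0) for a in range(40, 100)
             for y in (2008, 2009) for s in ("male", "female")],
            columns=["age", "year", "sex", "rate"])
        table = rs.lifetable.LifeTable(zero)
        cohort = make_exponential_cohort(150, seed=2)
        res = rs.ExcessHazardModel(cohort, table,
                                   rs.ModelSpec(baseline_df=2)).fit()
        times = np.array([1.0, 4.0])
        ac = res.marginal_all_cause_survival(times, ci=None)
        nr = res.marginal_relative_survival(times, ci=None)
        np.testing.assert_allclose(ac.estimate, nr.estimate, rtol=1e-12)

    def test_no_excess_mortality_reduces_to_expected_survival(
            self, forced_exponential_results, constant_table):
        res = forced_exponential_results
        # intercept -200: Lambda ~ e^-200, R = 1 to double precision
        null = rs.ExcessHazardResults(res.model, np.array([-200.0, 1.0]),
                                      res.cov, res.diagnostics)
        times = np.array([1.0, 5.0])
        ac = null.marginal_all_cause_survival(times, ci=None)
        np.testing.assert_allclose(ac.estimate, np.exp(-CONST_MU * times),
                                   rtol=1e-10)

    def test_product_of_exponentials_closed_form(
            self, forced_exponential_results):
        times = np.array([1.0, 5.0])
        ac = forced_exponential_results.marginal_all_cause_survival(
            times, ci=None)
        np.testing.assert_allclose(
            ac.estimate, np.exp(-(CONST_LAM0 + CONST_MU) * times), rtol=1e-10)


class TestCrudeProbabilities:
    def test_competing_exponentials_closed_form(
            self, forced_exponential_results):
        times = np.array([1.0, 2.5, 5.0])
        tot = CONST_LAM0 + CONST_MU
        cc = forced_exponential_results.marginal_crude_probability(
            times, "cancer", ci=None, n_nodes=100)
        np.testing.assert_allclose(
            cc.estimate, CONST_LAM0 / tot * (1 - np.exp(-tot * times)),
            atol=1e-6)
        co = forced_exponential_results.marginal_crude_probability(
            times, "other", ci=None, n_nodes=100)
        np.testing.assert_allclose(
            co.estimate, CONST_MU / tot * (1 - np.exp(-tot * times)),
            atol=1e-6)

    def test_zero_time_has_zero_probability(self, forced_exponential_results):
        cc = forced_exponential_results.marginal_crude_probability(
            np.array([0.0, 1.0]), "cancer", ci=None)
        assert cc.estimate[0] == 0.0
        assert cc.estimate[1] > 0.0

    @pytest.mark.parametrize("fixture_name,tol30,tol100", [
        ("forced_exponential_results", 1e-4, 1e-6),
        ("scenario_a", 1e-4, 1e-6),
    ])
    def test_partition_identity_converges_with_nodes(
            self, request, fixture_name, tol30, tol100):
        """cancer + other + all-cause survival = 1, tightening with the
        quadrature node budget (10 -> 30 -> 100)."""
        obj = request.getfixturevalue(fixture_name)
        results = obj[0] if isinstance(obj, tuple) else obj
        times = np.array([0.5, 1.0, 2.5, 5.0])
        ac = results.marginal_all_cause_survival(times, ci=None)
        errs = {}
        for n_nodes in (10, 30, 100):
            cc = results.marginal_crude_probability(times, "cancer", ci=None,
                                                    n_nodes=n_nodes)
            co = results.marginal_crude_probability(times, "other", ci=None,
                                                    n_nodes=n_nodes)
            errs[n_nodes] = np.abs(cc.estimate + co.estimate
                                   + ac.estimate - 1.0).max()
        assert errs[30] < tol30
        assert errs[100] < tol100
        assert errs[100] <= errs[10]

    def test_crude_probabilities_non_decreasing(self, scenario_a):
        results, _ = scenario_a
        times = np.linspace(0.0, 5.0, 11)
        for cause in ("cancer", "other"):
            c = results.marginal_crude_probability(times, cause, ci=None)
            assert (np.diff(c.estimate) >= -1e-12).all()
            assert (c.estimate >= 0).all() and (c.estimate <= 1).all()


class TestExpectedProbability:
    def test_constant_rate_closed_form(self, exp_results, constant_table):
        times = np.array([0.0, 1.0, 5.0])
        c = std.marginal_expected_probability(
            constant_table, exp_results.model.cohort, times)
        np.testing.assert_allclose(c.estimate, 1.0 - np.exp(-CONST_MU * times),
                                   rtol=0, atol=1e-12)

    def test_single_patient_equals_own_expectation(self, constant_table):
        cohort = make_exponential_cohort(50, seed=8)
        one = cohort.data.iloc[[0]]
        times = np.array([2.0, 4.0])
        c = std.marginal_expected_probability(constant_table, cohort, times,
                                              subset=one)
        traj = constant_table.expected_survival(
            one["age"].iloc[0], 2008, one["sex"].iloc[0], eval_times=times)
        np.testing.assert_allclose(c.estimate, 1.0 - traj.survival, rtol=1e-12)

    def test_matches_mean_of_expected_trajectories(self, constant_table):
        cohort = make_exponential_cohort(40, seed=9)
        times = np.array([1.0, 3.0, 5.0])
        c = std.marginal_expected_probability(constant_table, cohort, times)
        ages, years, sexes, strata = cohort.z1_records()
        surv = np.vstack([
            constant_table.expected_survival(ages[i], years[i], sexes[i],
                                             strata[i], times).survival
            for i in range(cohort.n)])
        np.testing.assert_allclose(c.estimate, 1.0 - surv.mean(axis=0),
                                   rtol=1e-12)


class TestIntervals:
    def test_delta_intervals_respect_probability_range(self, scenario_a):
        results, _ = scenario_a
        times = np.linspace(0.25, 5.0, 8)
        for as_prob in (False, True):
            c = results.marginal_relative_survival(times,
                                                   as_probability=as_prob)
            assert (c.ci_lower >= 0).all() and (c.ci_upper <= 1).all()
            assert (c.ci_lower <= c.estimate).all()
            assert (c.estimate <= c.ci_upper).all()

    def test_output_table_has_interval_columns(self, scenario_a):
        results, _ = scenario_a
        frame = results.marginal_relative_survival(
            np.array([1.0, 5.0])).to_frame()
        assert list(frame.columns) == ["measure", "population", "x_override",
                                       "time", "estimate", "se", "ci_low",
                                       "ci_high"]
        assert frame["se"].notna().all()
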