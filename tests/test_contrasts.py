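"""Counterfactual contrasts and avoidable deaths."""

import numpy as np
import pandas as pd
import pytest

import relstand as rs
from tests.conftest import make_constant_table, make_exponential_cohort


@pytest.fixture(scope="module")
def no_exposure_results():
    """Fit on a cohort that declares no exposure column."""
    base = make_exponential_cohort(200, seed=17)
    cohort = rs.Cohort(base.data.drop(columns="x"))
    return rs.ExcessHazardModel(cohort, make_constant_table(),
                                rs.ModelSpec(baseline_df=1)).fit()


@pytest.fixture(scope="module")
def two_group_results():
    """Constant-hazard two-group fit: excess 0.2 vs 0.3, mu = 0.02."""
    cohort = make_exponential_cohort(4000, beta_x=np.log(1.5), seed=21)
    table = make_constant_table()
    spec = rs.ModelSpec(baseline_df=1, terms=[rs.linear("x")])
    return rs.ExcessHazardModel(cohort, table, spec).fit()


def zeroed_exposure(results, name="dep"):
    """Copy of the results with the exposure coefficient(s) set to zero."""
    params = results.params.copy()
    for j, nm in enumerate(results.model.design.column_names):
        if nm == name or nm.startswith(f"{name}:"):
            params[j] = 0.0
    return rs.ExcessHazardResults(results.model, params, results.cov,
                                  results.diagnostics)


class TestMarginalDifference:
    def test_null_exposure_effect_gives_zero_difference(self, scenario_a):
        results, _ = scenario_a
        null = zeroed_exposure(results)
        d = null.marginal_difference(np.array([1.0, 3.0, 5.0]),
                                     measure="net_probability",
                                     scenario="vary_both", ci=None)
        np.testing.assert_allclose(d.difference, 0.0, atol=1e-14)

    def test_difference_equals_curve_difference_exactly(self, scenario_a):
        results, _ = scenario_a
        times = np.array([0.5, 2.0, 5.0])
        d = results.marginal_difference(times, measure="net_probability",
                                        scenario="vary_both", ci=None)
        np.testing.assert_array_equal(
            d.difference, d.exposed.estimate - d.unexposed.estimate)

    def test_constant_hazard_difference_matches_closed_form(
            self, two_group_results):
        # truth: net probabilities 1-exp(-0.3 t) vs 1-exp(-0.2 t)
        d = two_group_results.marginal_difference(
            np.array([5.0]), measure="net_probability", scenario="vary_both")
        expected = np.exp(-1.0) - np.exp(-1.5)
        assert abs(d.difference[0] - expected) < 2 * d.se[0]

    def test_standardized_difference_equals_mean_conditional_difference(
            self, scenario_a):
        """Linearity: the difference of standardized curves equals the
        standardized difference of conditional predictions."""
        results, _ = scenario_a
        times = np.array([1.0, 5.0])
        d = results.marginal_difference(times, measure="net_probability",
                                        scenario="vary_both", ci=None)
        r1 = results.predict_relative_survival(times=times, x_override=1)
        r0 = results.predict_relative_survival(times=times, x_override=0)
        np.testing.assert_allclose(d.difference,
                                   ((1 - r1) - (1 - r0)).mean(axis=0),
                                   rtol=1e-12)

    def test_within_exposed_contrast_is_contrast_on_exposed_subset(
            self, scenario_a):
        results, _ = scenario_a
        times = np.array([1.0, 5.0])
        d = results.marginal_difference(times, measure="all_cause_probability",
                                        population="exposed",
                                        scenario="vary_r_only", ci=None)
        data = results.model.cohort.data
        sub = data[data["dep"] == 1].reset_index(drop=True)
        c1 = results.marginal_all_cause_survival(times, subset=sub,
                                                 x_override=1, ci=None)
        c0 = results.marginal_all_cause_survival(times, subset=sub,
                                                 x_override=0, ci=None)
        np.testing.assert_allclose(
            d.difference,
            (1 - c1.estimate) - (1 - c0.estimate), rtol=1e-12)

    def test_vary_r_only_equals_vary_both_without_exposure_stratified_table(
            self, two_group_results):
        """When the life table ignores the exposure, S* is identical under
        both scenarios by construction."""
        times = np.array([1.0, 5.0])
        kw = dict(measure="all_cause_probability", ci=None)
        d_r = two_group_results.marginal_difference(times,
                                                    scenario="vary_r_only",
                                                    **kw)
        d_b = two_group_results.marginal_difference(times,
                                                    scenario="vary_both",
                                                    **kw)
        np.testing.assert_allclose(d_r.difference, d_b.difference, rtol=1e-12)

    def test_vary_scenarios_differ_with_exposure_stratified_table(
            self, scenario_a):
        # scenario A's life table is deprivation-stratified (x1.3 rates)
        results, _ = scenario_a
        times = np.array([5.0])
        kw = dict(measure="all_cause_probability", population="exposed",
                  ci=None)
        d_r = results.marginal_difference(times, scenario="vary_r_only", **kw)
        d_b = results.marginal_difference(times, scenario="vary_both", **kw)
        assert abs(d_r.difference[0] - d_b.difference[0]) > 1e-4

    def test_net_measure_with_vary_r_only_is_an_error(self, scenario_a):
        results, _ = scenario_a
        with pytest.raises(ValueError, match="vary_r_only"):
            results.marginal_difference([5.0], measure="net_probability",
                                        scenario="vary_r_only")

    def test_missing_exposure_column_is_an_error(self, no_exposure_results):
        with pytest.raises(ValueError, match="exposure"):
            no_exposure_results.marginal_difference(
                [5.0], measure="net_probability", scenario="vary_both")


class TestTypicalYearCount:
    @pytest.fixture()
    def multi_year_results(self):
        cohort = make_exponential_cohort(600, beta_x=np.log(1.5), seed=31)
        cohort.data.loc[:299, "year"] = 2007
        table = make_constant_table()
        spec = rs.ModelSpec(baseline_df=1, terms=[rs.linear("x")])
        return rs.ExcessHazardModel(rs.Cohort(cohort.data, exposure="x"),
                                    table, spec).fit()

    def test_latest_year_and_per_year_rules(self, multi_year_results):
        data = multi_year_results.model.cohort.data
        latest = ((data["year"] == 2008) & (data["x"] == 1)).sum()
        assert rs.typical_year_count(multi_year_results,
                                     "latest_year") == latest
        assert rs.typical_year_count(multi_year_results, "per_year") == \
            pytest.approx((data["x"] == 1).sum() / 2)
        assert rs.typical_year_count(multi_year_results, 1234.0) == 1234.0

    def test_invalid_n_star_rejected(self, multi_year_results):
        with pytest.raises(ValueError):
            rs.typical_year_count(multi_year_results, -5)
        with pytest.raises(ValueError):
            rs.typical_year_count(multi_year_results, "sometimes")


class TestAvoidableDeaths:
    def test_self_contrast_is_identically_zero(self, scenario_a):
        results, _ = scenario_a
        ad = results.avoidable_deaths(np.array([1.0, 5.0]), n_star=1000.0,
                                      reference_level=1, ci=None)
        np.testing.assert_array_equal(ad.avoidable, 0.0)

    def test_linear_in_n_star(self, scenario_a):
        results, _ = scenario_a
        times = np.array([1.0, 3.0, 5.0])
        ad1 = results.avoidable_deaths(times, n_star=500.0, ci=None,
                                       partition=False)
        ad2 = results.avoidable_deaths(times, n_star=1000.0, ci=None,
                                       partition=False)
        np.testing.assert_allclose(ad2.avoidable, 2.0 * ad1.avoidable,
                                   rtol=1e-12)

    def test_zero_at_time_zero(self, scenario_a):
        results, _ = scenario_a
        ad = results.avoidable_deaths(np.array([0.0, 5.0]), n_star=1000.0,
                                      ci=None, partition=False)
        assert ad.avoidable[0] == 0.0

    def test_constant_hazard_closed_form(self, two_group_results):
        # mu = 0.02 in both groups; excess 0.3 (X=1) vs 0.2 (X=0):
        # AD(t) = N* (exp(-0.22 t) - exp(-0.32 t))
        times = np.array([1.0, 3.0, 5.0])
        ad = two_group_results.avoidable_deaths(times, n_star=1000.0,
                                                partition=False)
        expected = 1000.0 * (np.exp(-0.22 * times) - np.exp(-0.32 * times))
        assert (np.abs(ad.avoidable - expected) < 2 * ad.se).all()

    def test_partition_identity_and_reallocation_pattern(self, scenario_a):
        """Cancer partition minus the other-cause increase reproduces AD;
        patients spared the cancer die of other causes instead, so the
        other-cause increase is non-negative and grows with time."""
        results, _ = scenario_a
        times = np.linspace(0.0, 5.0, 6)
        ad = results.avoidable_deaths(times, n_star=1000.0, ci=None,
                                      n_nodes=30)
        np.testing.assert_allclose(
            ad.avoidable, ad.avoidable_cancer - ad.extra_other, atol=0.05)
        assert (ad.extra_other >= -1e-9).all()
        assert (np.diff(ad.extra_other) >= -1e-9).all()

    def test_delta_interval_brackets_estimate(self, scenario_a):
        results, _ = scenario_a
        times = np.array([1.0, 5.0])
        ad = results.avoidable_deaths(times, n_star=1000.0, partition=False)
        assert (ad.ci_lower <= ad.avoidable).all()
        assert (ad.avoidable <= ad.ci_upper).all()

    def test_no_exposed_patients_is_an_error(self, no_exposure_results):
        with pytest.raises(ValueError, match="exposure"):
            no_exposure_results.avoidable_deaths([5.0], n_star=100.0)
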