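"""Causal contrasts between exposure levels and avoidable-deaths measures.

Contrasts compare counterfactual standardized curves in which *everyone*
in the standardization set is first forced to exposure level 1 and then
to level 0, averaging over the same covariate distribution both times -
so the difference is not confounded by differences in the covariate mix
of the two groups.  Under conditional exchangeability, consistency and
positivity the difference estimates the average causal effect of the
exposure on the chosen scale.

Two scenario flavours exist for measures that involve the expected
survival S*:

* ``vary_both``: the exposure is also switched in the life-table lookup
  (only meaningful when the exposure is one of the life-table strata) -
  both cancer-related and other-cause differences are varied;
* ``vary_r_only``: S* is held at the standardization set's own
  characteristics and only the relative survival is switched - the
  "eliminate cancer-related differences" scenario.

Avoidable deaths scale the all-cause scenario contrast among the
exposed to N*, the number of exposed patients diagnosed in a typical
calendar year:

    AD(t) = D1(t | X=1) - D_R0(t | X=1),
    D_x(t) = N* * (1 - mean_{i in exposed} S*(t | z1_i) R(t | X=x, z2_i)).

AD partitions into avoidable cancer deaths minus the increase in
other-cause deaths (patients saved from the cancer remain at risk of
dying of other causes), both computed from crude-probability contrasts
scaled by N*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import standardize, uncertainty
from .standardize import StandardizedCurve

logger = logging.getLogger(__name__)

__all__ = ["ContrastResult", "AvoidableDeathsResult", "marginal_difference",
           "avoidable_deaths", "typical_year_count"]

_MEASURES = {
    "relative_survival": dict(fn="rs", as_probability=False),
    "net_probability": dict(fn="rs", as_probability=True),
    "all_cause_survival": dict(fn="ac", as_probability=False),
    "all_cause_probability": dict(fn="ac", as_probability=True),
    "crude_cancer": dict(fn="crude", cause="cancer"),
    "crude_other": dict(fn="crude", cause="other"),
}

_NET_MEASURES = ("relative_survival", "net_probability")


@dataclass
class ContrastResult:
    """Counterfactual curves under X=1 and X=0 and their difference."""

    measure: str
    times: np.ndarray
    exposed: StandardizedCurve        # everyone forced to X=1
    unexposed: StandardizedCurve      # everyone forced to X=0
    difference: np.ndarray
    se: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    population: str = "all"
    scenario: str = "vary_r_only"
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "measure": self.measure,
            "population": self.population,
            "scenario": self.scenario,
            "time": self.times,
            "x1": self.exposed.estimate,
            "x0": self.unexposed.estimate,
            "difference": self.difference,
        })
        df["se"] = self.se if self.se is not None else np.nan
        df["ci_low"] = self.ci_lower if self.ci_lower is not None else np.nan
        df["ci_high"] = self.ci_upper if self.ci_upper is not None else np.nan
        return df


def _population_subset(results, population: str, warn: bool = True):
    cohort = results.model.cohort
    if cohort.exposure is None:
        raise ValueError("cohort declares no exposure column")
    x = cohort.data[cohort.exposure].to_numpy()
    if population == "all":
        mask = np.ones(len(x), bool)
    elif population in ("exposed", "x1"):
        mask = x == 1
    elif population in ("unexposed", "x0"):
        mask = x == 0
    else:
        raise ValueError("population must be 'all', 'exposed' or 'unexposed'")
    if not mask.any():
        raise ValueError(f"standardization population {population!r} is empty")
    for level in (0, 1) if warn else ():
        if not (x[mask] == level).any():
            logger.warning(
                "exposure level %d absent from the %s standardization set; "
                "the positivity assumption may fail", level, population)
    return cohort.data.loc[mask].reset_index(drop=True)


def _measure_point(results, records, times, measure, x, scenario, weights,
                   n_nodes):
    info = _MEASURES[measure]
    x_exp = x if scenario == "vary_both" else None
    if info["fn"] == "rs":
        def point(params):
            r = standardize._rs_matrix(results, records, times, x, params)
            w = standardize._resolve_weights(weights, len(records))
            m = (w[:, None] * r).mean(axis=0)
            return 1.0 - m if info["as_probability"] else m
        return point
    if info["fn"] == "ac":
        sstar = standardize._expected_survival_matrix(
            results, standardize._override_expected(results, records, x_exp),
            times)

        def point(params):
            r = standardize._rs_matrix(results, records, times, x, params)
            w = standardize._resolve_weights(weights, len(records))
            m = (w[:, None] * sstar * r).mean(axis=0)
            return 1.0 - m if info["as_probability"] else m
        return point

    def point(params):
        f = standardize._crude_matrix(results, records, times, info["cause"],
                                      x, x_exp, n_nodes, params)
        w = standardize._resolve_weights(weights, len(records))
        return (w[:, None] * f).mean(axis=0)
    return point


def marginal_difference(results, times, measure: str = "net_probability",
                        population: str = "all",
                        scenario: str = "vary_r_only", weights=None,
                        ci="delta", level: float = 0.95,
                        n_nodes: int = 30) -> ContrastResult:
    """Difference of counterfactual standardized curves, X=1 minus X=0."""
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if scenario not in ("vary_both", "vary_r_only"):
        raise ValueError("scenario must be 'vary_both' or 'vary_r_only'")
    if measure in _NET_MEASURES and scenario == "vary_r_only":
        raise ValueError(
            "scenario='vary_r_only' is meaningless for net measures: they "
            "already exclude other-cause mortality; use scenario='vary_both'")
    times = np.asarray(times, dtype=float)
    records = _population_subset(results, population)
    p1 = _measure_point(results, records, times, measure, 1, scenario,
                        weights, n_nodes)
    p0 = _measure_point(results, records, times, measure, 0, scenario,
                        weights, n_nodes)

    curves = {}
    for x, point in ((1, p1), (0, p0)):
        est = point(results.params)
        curves[x] = StandardizedCurve(
            measure=measure, times=times, estimate=est, population=population,
            x_override=x, level=level)
        if ci == "delta":
            se, lo, hi = uncertainty.delta_interval(
                point, results.params, results.cov, level=level,
                transform=standardize.MEASURE_TRANSFORMS.get(measure,
                                                             "identity"),
                names=results.model.design.column_names)
            curves[x].se, curves[x].ci_lower, curves[x].ci_upper = se, lo, hi

    diff_point = lambda params: p1(params) - p0(params)
    result = ContrastResult(
        measure=measure, times=times, exposed=curves[1], unexposed=curves[0],
        difference=curves[1].estimate - curves[0].estimate,
        population=population, scenario=scenario, level=level)
    if ci == "delta":
        se, lo, hi = uncertainty.delta_interval(
            diff_point, results.params, results.cov, level=level,
            transform="identity",
            names=results.model.design.column_names)
        result.se, result.ci_lower, result.ci_upper = se, lo, hi
    return result


def typical_year_count(results, rule="latest_year") -> float:
    """N*: exposed patients diagnosed in a typical calendar year.

    ``rule``: ``"latest_year"`` counts exposed patients diagnosed in the
    most recent calendar year; ``"per_year"`` divides the exposed total
    by the number of distinct diagnosis years; a number overrides both.
    """
    if isinstance(rule, (int, float, np.integer, np.floating)):
        if rule <= 0:
            raise ValueError("N* must be > 0")
        return float(rule)
    cohort = results.model.cohort
    data = cohort.data
    exposed = data[data[cohort.exposure] == 1]
    if len(exposed) == 0:
        raise ValueError("no exposed patients in the cohort")
    if rule == "latest_year":
        return float((exposed[cohort.year] == data[cohort.year].max()).sum())
    if rule == "per_year":
        return float(len(exposed) / data[cohort.year].nunique())
    raise ValueError("n_star rule must be 'latest_year', 'per_year' or a number")


@dataclass
class AvoidableDeathsResult:
    """Avoidable deaths among the exposed under an imposed reference R."""

    times: np.ndarray
    n_star: float
    deaths_factual: np.ndarray       # D1(t | X=1)
    deaths_scenario: np.ndarray      # D_R0(t | X=1)
    avoidable: np.ndarray            # AD = D1 - D_R0
    avoidable_cancer: np.ndarray     # N* x crude-cancer contrast
    extra_other: np.ndarray          # N* x increase in other-cause deaths (>= 0 typically)
    se: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    reference_level: object = 0
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.times,
            "deaths_factual": self.deaths_factual,
            "deaths_scenario": self.deaths_scenario,
            "avoidable_deaths": self.avoidable,
            "avoidable_cancer_deaths": self.avoidable_cancer,
            "extra_other_deaths": self.extra_other,
        })
        df["se"] = self.se if self.se is not None else np.nan
        df["ci_low"] = self.ci_lower if self.ci_lower is not None else np.nan
        df["ci_high"] = self.ci_upper if self.ci_upper is not None else np.nan
        df.insert(0, "n_star", self.n_star)
        return df


def avoidable_deaths(results, times, n_star="latest_year",
                     reference_level=0, ci="delta", level: float = 0.95,
                     n_nodes: int = 30,
                     partition: bool = True) -> AvoidableDeathsResult:
    """Avoidable (postponable) deaths among the exposed if they had the
    reference group's relative survival, with their cause partition.

    The standardization set is the exposed group (their own covariates
    and their own expected survival throughout); only R is switched to
    ``reference_level``.  The partition multiplies the crude-probability
    contrasts by N*: ``avoidable = avoidable_cancer - extra_other``.
    """
    times = np.asarray(times, dtype=float)
    records = _population_subset(results, "exposed", warn=False)
    nstar = typical_year_count(results, n_star)

    sstar = standardize._expected_survival_matrix(results, records, times)

    def deaths(x):
        def point(params):
            r = standardize._rs_matrix(results, records, times, x, params)
            return nstar * (1.0 - (sstar * r).mean(axis=0))
        return point

    d1_point = deaths(1)
    d0_point = deaths(reference_level)
    ad_point = lambda params: d1_point(params) - d0_point(params)

    d1 = d1_point(results.params)
    d0 = d0_point(results.params)
    out = AvoidableDeathsResult(
        times=times, n_star=nstar, deaths_factual=d1, deaths_scenario=d0,
        avoidable=d1 - d0, avoidable_cancer=np.zeros_like(d1),
        extra_other=np.zeros_like(d1), reference_level=reference_level,
        level=level)
    if partition:
        crude = {}
        for cause in ("cancer", "other"):
            crude[cause] = {
                x: standardize._crude_matrix(
                    results, records, times, cause, x, None, n_nodes,
                    results.params).mean(axis=0)
                for x in (1, reference_level)
            }
        out.avoidable_cancer = nstar * (
            crude["cancer"][1] - crude["cancer"][reference_level])
        out.extra_other = nstar * (
            crude["other"][reference_level] - crude["other"][1])
    if ci == "delta":
        se, lo, hi = uncertainty.delta_interval(
            ad_point, results.params, results.cov, level=level,
            transform="identity", names=results.model.design.column_names)
        out.se, out.ci_lower, out.ci_upper = se, lo, hi
    return out
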