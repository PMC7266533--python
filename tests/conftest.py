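"""Shared fixtures: toy life tables and simulated cohorts with known truth."""

import numpy as np
import pandas as pd
import pytest

import relstand as rs

CONST_MU = 0.02       # constant expected rate of the toy life table
CONST_LAM0 = 0.2      # constant excess hazard of the exponential cohorts


def make_constant_table(mu=CONST_MU):
    """Life table with the same rate in every cell (no age/year structure)."""
    return rs.make_toy_life_table(
        ages=range(18, 100), years=range(2008, 2015),
        sexes=("female", "male"), a=mu, b=0.0,
    )


def make_exponential_cohort(n, lam0=CONST_LAM0, mu=CONST_MU, beta_x=0.0,
                            censoring=5.0, seed=0):
    """Cohort with constant excess hazard lam0*exp(beta_x*x) and constant
    other-cause rate mu; exposure balanced when beta_x is used."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    tc = rng.exponential(1.0 / (lam0 * np.exp(beta_x * x)), n)
    to = rng.exponential(1.0 / mu, n)
    t = np.maximum(np.minimum(np.minimum(tc, to), censoring), 1e-6)
    d = (t < censoring).astype(int)
    data = pd.DataFrame({
        "time": t, "event": d, "age": rng.uniform(40, 80, n),
        "sex": rng.choice(["male", "female"], n), "year": 2008, "x": x,
    })
    return rs.Cohort(data, exposure="x")


@pytest.fixture(scope="session")
def constant_table():
    return make_constant_table()


@pytest.fixture(scope="session")
def exp_results(constant_table):
    """df=1 exponential-excess fit on a constant-hazard cohort, n=2000."""
    cohort = make_exponential_cohort(2000, seed=42)
    model = rs.ExcessHazardModel(cohort, constant_table,
                                 rs.ModelSpec(baseline_df=1))
    return model.fit()


@pytest.fixture(scope="session")
def scenario_a():
    """Scenario A: Weibull excess hazard, exposure hazard ratio 1.5,
    Gompertz expected rates, n=2000; returns (results, truth)."""
    sc = rs.SimulationScenario(n=2000, seed=11)
    cohort, table, truth = rs.simulate_cohort(sc)
    spec = rs.ModelSpec(baseline_df=3,
                        terms=[rs.linear("dep"), rs.linear("age")])
    results = rs.ExcessHazardModel(cohort, table, spec).fit()
    return results, truth


@pytest.fixture(scope="session")
def forced_exponential_results(constant_table):
    """Results whose coefficients are *set* (not fitted) so that
    Lambda(t) = 0.2 t exactly: eta = ln 0.2 + ln t on an
    unorthogonalized df=1 basis.  Closed forms are then exact."""
    cohort = make_exponential_cohort(200, seed=7)
    model = rs.ExcessHazardModel(
        cohort, constant_table,
        rs.ModelSpec(baseline_df=1, orthogonalize=False))
    params = np.array([np.log(CONST_LAM0), 1.0])
    return rs.ExcessHazardResults(model, params, np.eye(2) * 1e-4,
                                  {"loglike": np.nan, "grad_norm": 0.0,
                                   "iterations": 0})
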