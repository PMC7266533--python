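"""Synthetic cohorts and toy life tables with known excess-hazard truth.

The generator emulates the structure of a population-based colon-cancer
cohort: two deprivation groups (the most deprived group is the exposure,
X=1), both sexes, ages 18-99 drawn from registry-like age bands, a
single diagnosis year and administrative censoring after five years.
Expected (other-cause) rates follow a Gompertz curve in age with sex and
deprivation multipliers; the excess hazard is Weibull with a log-linear
age effect, a proportional exposure effect and an optional
time-dependent exposure effect:

    lambda(t | age, x) = lambda0 * kappa * t^(kappa-1)
                         * exp(beta_age * (age-70)/10
                               + (beta_exposure + beta_td * ln t) * x)

Potential times to death from cancer and from other causes are drawn
independently given covariates (the conditional-independence assumption
of the relative-survival framework); the observed record keeps only the
all-cause event indicator, as relative survival requires no cause of
death, while the true cause is retained on the truth object for oracle
checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .lifetable import LifeTable

__all__ = ["SimulationScenario", "TruthFunctions", "make_toy_life_table",
           "simulate_cohort"]

# pooled age-band proportions and sex split of the illustrative
# colon-cancer study population
_AGE_BANDS = (
    (18, 45, 0.0297),
    (45, 55, 0.0570),
    (55, 65, 0.1756),
    (65, 75, 0.2887),
    (75, 85, 0.3236),
    (85, 99, 0.1254),
)


@dataclass
class SimulationScenario:
    """All knobs of the data-generating process (defaults: scenario A)."""

    n: int = 2000
    exposure_prevalence: float = 0.445
    age_bands: tuple = _AGE_BANDS
    female_prop: float = 0.468
    diagnosis_year: int = 2008
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.09
    sex_multipliers: dict = field(
        default_factory=lambda: {"male": 1.0, "female": 0.6})
    stratum_multipliers: dict = field(default_factory=lambda: {0: 1.0, 1: 1.3})
    rate_cap: float = 0.7
    lambda0: float = 0.15
    kappa: float = 0.9
    beta_exposure: float = math.log(1.5)
    beta_age: float = 0.25          # per decade of age, centred at 70
    beta_td: float = 0.0            # time-dependent exposure effect (x ln t)
    censoring_time: float = 5.0
    other_rate_multiplier: float = 1.0   # life-table misspecification switch
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.exposure_prevalence < 1.0):
            raise ValueError("exposure prevalence must be in (0, 1)")
        if self.lambda0 <= 0 or self.kappa <= 0 or self.gompertz_a <= 0:
            raise ValueError("rates must be positive")
        if self.kappa + self.beta_td <= 0:
            raise ValueError("kappa + beta_td must be positive")

    @classmethod
    def illustrative(cls, n: int = 7346, seed: int = 0) -> "SimulationScenario":
        """Emulation of the illustrative study: a time-dependent
        (diminishing) deprivation effect on the excess hazard."""
        return cls(n=n, beta_td=-0.2, seed=seed)

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["age_bands"] = [list(b) for b in self.age_bands]
        d["stratum_multipliers"] = {str(k): v
                                    for k, v in self.stratum_multipliers.items()}
        return d


def make_toy_life_table(
    ages=range(18, 100),
    years=range(2008, 2015),
    sexes=("female", "male"),
    strata: dict | None = None,
    a: float = 5e-5,
    b: float = 0.09,
    sex_multipliers: dict | None = None,
    stratum_multipliers: dict | None = None,
    cap: float = 0.7,
) -> LifeTable:
    """Gompertz life table: rate = a * exp(b * age) * multipliers, capped."""
    strata = strata or {}
    sex_multipliers = sex_multipliers or {}
    stratum_multipliers = stratum_multipliers or {}
    rows = []
    stratum_names = list(strata)
    combos = [()]
    for name in stratum_names:
        combos = [c + (lv,) for c in combos for lv in strata[name]]
    for sex in sexes:
        for combo in combos:
            mult = sex_multipliers.get(sex, 1.0)
            for lv in combo:
                mult *= stratum_multipliers.get(lv, 1.0)
            for age in ages:
                rate = min(a * math.exp(b * age) * mult, cap)
                for year in years:
                    rows.append((age, year, sex, *combo, rate))
    df = pd.DataFrame(rows, columns=["age", "year", "sex", *stratum_names,
                                     "rate"])
    return LifeTable(df, strata=stratum_names)


def _scenario_life_table(sc: SimulationScenario) -> LifeTable:
    last_year = sc.diagnosis_year + int(math.ceil(sc.censoring_time)) + 1
    return make_toy_life_table(
        ages=range(18, 100),
        years=range(sc.diagnosis_year, last_year + 1),
        sexes=("female", "male"),
        strata={"dep": sorted(sc.stratum_multipliers)},
        a=sc.gompertz_a, b=sc.gompertz_b,
        sex_multipliers=sc.sex_multipliers,
        stratum_multipliers=sc.stratum_multipliers,
        cap=sc.rate_cap,
    )


@dataclass
class TruthFunctions:
    """Closed-form truth of a simulated scenario, for oracle checks."""

    scenario: SimulationScenario
    records: pd.DataFrame        # the simulated covariate draw
    life_table: LifeTable
    cause: np.ndarray            # 0 censored, 1 cancer, 2 other (internal)

    # -- conditional truth ----------------------------------------------
    def _lp0(self, age, x):
        sc = self.scenario
        return sc.beta_age * (np.asarray(age, float) - 70.0) / 10.0 \
            + sc.beta_exposure * np.asarray(x, float)

    def cum_excess_hazard(self, t, age, x):
        sc = self.scenario
        t = np.asarray(t, float)
        kx = sc.kappa + sc.beta_td * np.asarray(x, float)
        with np.errstate(divide="ignore"):
            out = sc.lambda0 * sc.kappa / kx * np.exp(self._lp0(age, x)) \
                * np.where(t > 0, t, 0.0) ** kx
        return out

    def relative_survival(self, t, age, x):
        return np.exp(-self.cum_excess_hazard(t, age, x))

    def excess_hazard(self, t, age, x):
        sc = self.scenario
        t = np.asarray(t, float)
        kx = sc.kappa + sc.beta_td * np.asarray(x, float)
        return sc.lambda0 * sc.kappa * np.exp(self._lp0(age, x)) \
            * t ** (kx - 1.0)

    def _inverse_cum(self, e, age, x):
        sc = self.scenario
        kx = sc.kappa + sc.beta_td * np.asarray(x, float)
        return (e * kx / (sc.lambda0 * sc.kappa * np.exp(self._lp0(age, x)))
                ) ** (1.0 / kx)

    # -- marginal truth by brute-force integration -----------------------
    def marginal(self, measure: str, times, population: str = "all",
                 x_override=None, n_steps: int = 10_001) -> np.ndarray:
        """True marginal measure over the simulated covariate draw.

        Crude probabilities use fine-grid trapezoid integration of the
        defining integrals with the exact expected survival.
        """
        times = np.asarray(times, dtype=float)
        df = self.records
        if population in ("exposed", "x1"):
            df = df[df["dep"] == 1]
        elif population in ("unexposed", "x0"):
            df = df[df["dep"] == 0]
        elif population != "all":
            raise ValueError("population must be 'all', 'exposed' or 'unexposed'")
        df = df.reset_index(drop=True)
        age = df["age"].to_numpy(float)
        x = df["dep"].to_numpy(float) if x_override is None \
            else np.full(len(df), float(x_override))

        if measure in ("relative_survival", "net_probability"):
            r = self.relative_survival(times[None, :], age[:, None],
                                       x[:, None]).mean(axis=0)
            return 1.0 - r if measure == "net_probability" else r

        t_max = float(times.max()) if times.size else 1e-9
        grid = np.linspace(0.0, max(t_max, 1e-9), n_steps)
        acc = np.zeros(times.size)
        for i in range(len(df)):
            path = self.life_table.hazard_path(
                age[i], df.loc[i, "year"], df.loc[i, "sex"],
                (df.loc[i, "dep"],), t_max=max(t_max, 1e-9))
            sstar = path.survival_at(grid)
            if measure in ("all_cause_survival", "all_cause_probability"):
                v = np.interp(times, grid, sstar) \
                    * self.relative_survival(times, age[i], x[i])
            elif measure == "expected_probability":
                v = np.interp(times, grid, sstar)
            elif measure in ("crude_cancer", "crude_other"):
                r = self.relative_survival(grid, age[i], x[i])
                if measure == "crude_cancer":
                    with np.errstate(divide="ignore", invalid="ignore"):
                        g = self.excess_hazard(grid, age[i], x[i])
                    g[0] = g[1] if np.isfinite(g[1]) else 0.0
                    if not np.isfinite(g[0]):
                        g[0] = 0.0
                else:
                    g = path.hazard_at(grid)
                integ = sstar * r * g
                cum = np.concatenate(
                    [[0.0], np.cumsum(0.5 * (integ[1:] + integ[:-1])
                                      * np.diff(grid))])
                v = np.interp(times, grid, cum)
            else:
                raise ValueError(f"unknown measure {measure!r}")
            acc += v
        acc /= len(df)
        if measure in ("all_cause_probability", "expected_probability"):
            return 1.0 - acc
        return acc


def simulate_cohort(scenario: SimulationScenario,
                    life_table: LifeTable | None = None):
    """Draw a cohort from the scenario.

    Returns ``(cohort, life_table, truth)``; other-cause death times are
    drawn from the same life table the model later uses for fitting
    (scaled by ``other_rate_multiplier`` for misspecification studies).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    table = life_table or _scenario_life_table(sc)

    # covariates
    probs = np.array([b[2] for b in sc.age_bands], float)
    probs = probs / probs.sum()
    band = rng.choice(len(sc.age_bands), size=sc.n, p=probs)
    lo = np.array([b[0] for b in sc.age_bands])[band]
    hi = np.array([b[1] for b in sc.age_bands])[band]
    age = lo + rng.random(sc.n) * (hi - lo)
    sex = np.where(rng.random(sc.n) < sc.female_prop, "female", "male")
    x = (rng.random(sc.n) < sc.exposure_prevalence).astype(int)
    records = pd.DataFrame({
        "id": np.arange(sc.n), "age": age, "sex": sex,
        "year": sc.diagnosis_year, "dep": x,
    })

    truth = TruthFunctions(scenario=sc, records=records, life_table=table,
                           cause=np.zeros(sc.n, int))

    # potential cancer death times (inverse transform of the Weibull
    # cumulative excess hazard)
    e_cancer = rng.exponential(size=sc.n)
    t_cancer = truth._inverse_cum(e_cancer, age, x)

    # potential other-cause death times from the piecewise-constant
    # expected hazard along the attained age/year path
    e_other = rng.exponential(size=sc.n)
    t_other = np.empty(sc.n)
    horizon = sc.censoring_time + 1.0
    for i in range(sc.n):
        path = table.hazard_path(age[i], sc.diagnosis_year, sex[i], (x[i],),
                                 t_max=horizon)
        cum = path.cum * sc.other_rate_multiplier
        if e_other[i] >= cum[-1]:
            t_other[i] = np.inf
        else:
            j = int(np.searchsorted(cum, e_other[i], side="right"))
            rate = path.rates[j - 1] * sc.other_rate_multiplier
            t_other[i] = path.breaks[j - 1] + (e_other[i] - cum[j - 1]) / rate
    t_obs = np.minimum.reduce([t_cancer, t_other, np.full(sc.n,
                                                          sc.censoring_time)])
    t_obs = np.maximum(t_obs, 1e-6)
    event = (t_obs < sc.censoring_time).astype(int)
    truth.cause = np.where(event == 0, 0, np.where(t_cancer <= t_other, 1, 2))

    data = records.copy()
    data["time"] = t_obs
    data["event"] = event
    cohort = Cohort(data, exposure="dep", lifetable_strata=("dep",))
    return cohort, table, truth
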